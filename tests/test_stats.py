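import math

import numpy as np
import pytest

from lorete.stats import (
    binom_tail,
    family_divergence,
    family_divergence_from_copies,
    k2p_distance,
    merge_intervals,
    min_significant,
    pairwise_PQ,
    trap_test,
)

from _oracles import binom_upper_tail, interval_fraction_and_membership


class TestPairwisePQ:
    def test_identical_sequences(self):
        assert pairwise_PQ("A" * 100, "A" * 100) == (0.0, 0.0)

    def test_single_transition(self):
        assert pairwise_PQ("AAAA", "GAAA") == (0.25, 0.0)

    def test_two_transversions(self):
        # columns: A/C (tv), A/A, A/T (tv), A/A
        assert pairwise_PQ("AAAA", "CATA") == (0.0, 0.5)

    def test_gap_and_n_columns_excluded(self):
        p, q = pairwise_PQ("A-GN", "AAGC")
        assert (p, q) == (0.0, 0.0)

    def test_all_excluded_raises(self):
        with pytest.raises(ValueError):
            pairwise_PQ("---", "NNN")

    @pytest.mark.parametrize(
        "a,b,is_transition",
        [("A", "G", True), ("C", "T", True), ("A", "C", False), ("G", "T", False)],
    )
    def test_substitution_classification(self, a, b, is_transition):
        p, q = pairwise_PQ(a * 4, b * 4)
        assert (p, q) == ((1.0, 0.0) if is_transition else (0.0, 1.0))


class TestK2P:
    def test_zero_differences_zero_distance(self):
        assert k2p_distance(0, 0) == 0.0

    def test_closed_form_worked_value(self):
        assert k2p_distance(0.1, 0.05) == pytest.approx(0.1702, abs=1e-4)

    def test_saturation_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            k2p_distance(0.5, 0.0)
        with pytest.raises(ValueError):
            k2p_distance(0.0, 0.5)

    def test_distance_bounds_and_monotonicity(self):
        rng = np.random.default_rng(9)
        prev = None
        for P in np.linspace(0.0, 0.3, 10):
            d = k2p_distance(P, 0.05)
            assert d >= P + 0.05 - 1e-12  # Jensen-type lower bound
            if prev is not None:
                assert d > prev
            prev = d


class TestFamilyDivergence:
    def test_identical_copies_zero(self):
        assert family_divergence([("ACGT" * 10, "ACGT" * 10)]) == (0.0, 0)

    def test_mean_of_two_copies(self):
        # craft copies with known P against a 100-nt consensus
        cons = "A" * 100
        copy1 = "G" * 10 + "A" * 90   # P = 0.10
        copy2 = "G" * 20 + "A" * 80   # P = 0.20
        d1 = k2p_distance(0.10, 0.0)
        d2 = k2p_distance(0.20, 0.0)
        mean, skipped = family_divergence([(copy1, cons), (copy2, cons)])
        assert mean == pytest.approx((d1 + d2) / 2)
        assert skipped == 0

    def test_saturated_copies_excluded_and_counted(self):
        cons = "A" * 10
        ok = ("GAAAAAAAAA", cons)
        saturated = ("G" * 10, cons)
        mean, skipped = family_divergence([ok, saturated])
        assert skipped == 1
        assert mean == pytest.approx(k2p_distance(0.1, 0.0))

    def test_all_saturated_raises(self):
        with pytest.raises(ValueError):
            family_divergence([("G" * 10, "A" * 10)])

    def test_simulated_rates_recovered(self):
        """Copies mutated at known ts/tv rates recover the expected mean d."""
        rng = np.random.default_rng(42)
        ts_rate, tv_rate = 0.06, 0.02
        cons = "".join(rng.choice(list("ACGT"), size=800))
        transit = {"A": "G", "G": "A", "C": "T", "T": "C"}
        transver = {"A": "C", "G": "T", "C": "A", "T": "G"}
        pairs = []
        for _ in range(60):
            copy = []
            for ch in cons:
                r = rng.random()
                if r < ts_rate:
                    copy.append(transit[ch])
                elif r < ts_rate + tv_rate:
                    copy.append(transver[ch])
                else:
                    copy.append(ch)
            pairs.append(("".join(copy), cons))
        mean, skipped = family_divergence(pairs)
        assert skipped == 0
        expected = k2p_distance(ts_rate, tv_rate)
        per_copy = [k2p_distance(*pairwise_PQ(a, b)) for a, b in pairs]
        se = np.std(per_copy, ddof=1) / math.sqrt(len(per_copy))
        assert abs(mean - expected) <= 3 * se

    def test_unaligned_copies_via_global_alignment(self):
        cons = "ACGTACGTACGTACGTACGT" * 5
        copy = cons[:40] + "G" + cons[41:]  # one A->G transition
        mean, skipped = family_divergence_from_copies([copy, cons], cons)
        assert skipped == 0
        assert mean == pytest.approx(k2p_distance(0.01, 0.0) / 2, rel=1e-6)


class TestBinomTail:
    def test_k_zero_is_one(self):
        assert binom_tail(50, 0.3, 0) == 1.0

    def test_worked_value_n10(self):
        assert binom_tail(10, 0.5, 9) == pytest.approx(11 / 1024)

    def test_p_zero(self):
        assert binom_tail(10, 0.0, 1) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binom_tail(10, 0.5, 11)
        with pytest.raises(ValueError):
            binom_tail(10, 1.5, 2)

    def test_agrees_with_enumeration_small_n(self):
        for n in (1, 5, 17, 30):
            for p in (0.0736, 0.25, 0.5, 0.9):
                for k in range(n + 1):
                    assert binom_tail(n, p, k) == pytest.approx(
                        binom_upper_tail(n, p, k), abs=1e-12
                    )

    def test_decreasing_in_k(self):
        values = [binom_tail(40, 0.2, k) for k in range(41)]
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestMinSignificant:
    def test_printed_minimal_count_for_gtwin_conditions(self):
        assert min_significant(93, 0.0736, 0.05) == 12

    def test_worked_value_n10_half(self):
        # P(X>=9) = 11/1024 < 0.05 while P(X>=8) = 56/1024 >= 0.05
        assert min_significant(10, 0.5) == 9

    def test_unreachable_returns_n_plus_one(self):
        assert min_significant(1, 0.9) == 2

    def test_monotone_in_alpha(self):
        assert min_significant(93, 0.0736, 0.01) >= min_significant(93, 0.0736, 0.05)


class TestTrapTest:
    def test_no_clusters(self):
        res = trap_test([10, 20, 30], [], 1000)
        assert (res.p, res.k, res.pvalue) == (0.0, 0, 1.0)

    def test_clusters_cover_genome(self):
        res = trap_test([10, 20], [(0, 1000)], 1000)
        assert res.p == 1.0
        assert res.k == 2
        assert res.pvalue == pytest.approx(1.0)

    def test_observed_study_scale_counts_not_significant(self):
        # 18 of 274 insertions inside clusters covering 7.36% of the genome
        genome = 1_000_000
        clusters = [(0, 73_600)]
        calls = [i * 100 for i in range(18)] + [500_000 + i for i in range(256)]
        res = trap_test(calls, clusters, genome)
        assert (res.n, res.k) == (274, 18)
        assert res.p == pytest.approx(0.0736)
        assert res.pvalue >= 0.05

    def test_merge_and_membership_against_bruteforce(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            genome = 10_000
            n_iv = int(rng.integers(1, 8))
            ivs = []
            for _ in range(n_iv):
                s = int(rng.integers(0, genome - 10))
                ivs.append((s, s + int(rng.integers(1, 500))))
            ivs = [(s, min(e, genome)) for s, e in ivs]
            calls = rng.integers(0, genome, size=40).tolist()
            res = trap_test(calls, ivs, genome)
            frac, inside = interval_fraction_and_membership(ivs, genome, calls)
            assert res.p == pytest.approx(frac)
            assert res.k == inside

    def test_merge_intervals_overlap_handling(self):
        assert merge_intervals([(5, 10), (0, 6), (20, 30)]) == [(0, 10), (20, 30)]

    def test_invalid_genome_length(self):
        with pytest.raises(ValueError):
            trap_test([1], [(0, 5)], 0)
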