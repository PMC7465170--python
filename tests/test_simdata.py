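import numpy as np
import pytest

from lorete.simdata import (
    ErrorProfile,
    SimRead,
    implant_insertions,
    long_reads,
    paired_reads,
    random_genome,
    to_mate_pairs,
)
from lorete.shortread_tei import cluster_pairs, find_discordant


class TestRandomGenome:
    def test_length_and_reproducibility(self):
        g1 = random_genome(10_000, seed=1)
        g2 = random_genome(10_000, seed=1)
        assert len(g1) == 10_000
        assert g1 == g2
        assert g1 != random_genome(10_000, seed=2)

    def test_extreme_gc(self):
        assert set(random_genome(500, gc=1.0, seed=0)) <= {"G", "C"}
        assert set(random_genome(500, gc=0.0, seed=0)) <= {"A", "T"}

    def test_empirical_gc_within_sampling_error(self):
        g = random_genome(100_000, gc=0.42, seed=3)
        gc = sum(c in "GC" for c in g) / len(g)
        se = np.sqrt(0.42 * 0.58 / 100_000)
        assert abs(gc - 0.42) <= 3 * se

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            random_genome(0)
        with pytest.raises(ValueError):
            random_genome(10, gc=1.5)


class TestErrorProfile:
    def test_total_and_split(self):
        p = ErrorProfile.from_total(0.05)
        assert p.total == pytest.approx(0.05)
        assert p.substitution_rate == pytest.approx(0.02)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            ErrorProfile(substitution_rate=0.3)
        with pytest.raises(ValueError):
            ErrorProfile(0.2, 0.2, 0.15)


class TestImplant:
    def test_tsd_duplication_adds_k(self, small_library):
        genome = random_genome(10_000, seed=4)
        modified, truth = implant_insertions(genome, small_library, [(5000, "ltrA")])
        te_len = len(small_library["ltrA"].sequence)
        assert len(modified) == 10_000 + te_len + 4
        t = truth[0]
        assert t.tsd == genome[5000:5004]
        # final locus reads [target][TE][target]
        locus = modified[5000 : 5004 + te_len + 4]
        assert locus == t.tsd + t.te_sequence + t.tsd

    def test_zero_sites_unchanged(self, small_library):
        genome = random_genome(1000, seed=5)
        modified, truth = implant_insertions(genome, small_library, [])
        assert modified == genome and truth == []

    def test_minor_frequency_leaves_genome_unchanged(self, small_library):
        genome = random_genome(10_000, seed=6)
        modified, truth = implant_insertions(
            genome, small_library, [(5000, "ltrA")], frequency=0.1
        )
        assert modified == genome
        assert truth[0].frequency == 0.1

    def test_overlapping_sites_rejected(self, small_library):
        genome = random_genome(10_000, seed=7)
        with pytest.raises(ValueError, match="overlap"):
            implant_insertions(
                genome, small_library, [(5000, "ltrA"), (5002, "ltrB")]
            )

    def test_site_near_end_rejected(self, small_library):
        genome = random_genome(1000, seed=8)
        with pytest.raises(ValueError):
            implant_insertions(genome, small_library, [(999, "ltrA")])


def apply_cigar(read: SimRead, genome: str) -> str:
    """Reconstruct the read from the genome and its true alignment."""
    out = []
    ref = read.ref_start
    q = 0
    for op, ln in read.cigar:
        if op == "M":
            out.append(genome[ref : ref + ln])
            ref += ln
            q += ln
        elif op in ("I", "S"):
            out.append(read.sequence[q : q + ln])
            q += ln
        elif op == "D":
            ref += ln
    return "".join(out)


class TestLongReads:
    def test_error_free_reads_are_genome_substrings(self):
        genome = random_genome(30_000, seed=9)
        reads = long_reads(genome, coverage=5, mean_len=3000, seed=10)
        for r in reads:
            assert r.cigar == (("M", len(r.sequence)),)
            assert r.sequence == genome[r.ref_start : r.ref_start + len(r.sequence)]

    def test_total_bases_close_to_coverage(self):
        genome = random_genome(50_000, seed=11)
        reads = long_reads(genome, coverage=25, mean_len=4000, seed=12)
        total = sum(len(r.sequence) for r in reads)
        assert abs(total - 25 * 50_000) <= 0.1 * 25 * 50_000

    def test_seed_reproducibility(self):
        genome = random_genome(20_000, seed=13)
        r1 = long_reads(genome, coverage=3, mean_len=2000, seed=14)
        r2 = long_reads(genome, coverage=3, mean_len=2000, seed=14)
        assert r1 == r2

    def test_cigar_consistency_with_errors(self):
        genome = random_genome(30_000, seed=15)
        # indel-only profile: the true alignment must reconstruct each read
        # from the genome exactly (M from genome, I/S from the read)
        profile = ErrorProfile(insertion_rate=0.03, deletion_rate=0.03)
        reads = long_reads(genome, coverage=4, mean_len=3000, profile=profile, seed=16)
        assert any(len(r.cigar) > 1 for r in reads)
        for r in reads:
            q_len = sum(ln for op, ln in r.cigar if op in ("M", "I", "S"))
            assert q_len == len(r.sequence)
            assert apply_cigar(r, genome) == r.sequence

    def test_query_length_consistent_with_substitutions(self):
        genome = random_genome(20_000, seed=30)
        reads = long_reads(
            genome, coverage=3, mean_len=2000,
            profile=ErrorProfile.from_total(0.08), seed=31,
        )
        for r in reads:
            q_len = sum(ln for op, ln in r.cigar if op in ("M", "I", "S"))
            assert q_len == len(r.sequence)

    def test_minor_insertion_carried_at_designated_fraction(self, small_library):
        genome = random_genome(60_000, seed=17)
        _, truth = implant_insertions(
            genome, small_library, [(30_000, "ltrA")], frequency=0.1
        )
        reads = long_reads(
            genome, truth, coverage=40, mean_len=6000, seed=18
        )
        bp = truth[0].insertion_point
        ilen = len(truth[0].inserted_sequence)
        spanning = [
            r
            for r in reads
            if r.ref_start <= bp - 200
            and r.ref_start + sum(l for op, l in r.cigar if op in "MI")
            >= bp + 200 + (ilen if r.carried_sites else 0)
        ]
        carriers = [r for r in reads if r.carried_sites]
        assert carriers, "spanning molecules must include carriers"
        frac = len(carriers) / max(1, len(spanning))
        assert 0.05 <= frac <= 0.2
        # carrier reads contain the full inserted sequence
        for r in carriers:
            assert truth[0].inserted_sequence in r.sequence


class TestPairedReads:
    def test_without_insertions_no_discordant_truth(self):
        genome = random_genome(20_000, seed=19)
        pairs = paired_reads(genome, n_pairs=300, seed=20)
        assert all(p.concordant for p in pairs)
        assert find_discordant(to_mate_pairs(pairs)) == []

    def test_deterministic_under_seed(self):
        genome = random_genome(20_000, seed=21)
        assert paired_reads(genome, n_pairs=50, seed=22) == paired_reads(
            genome, n_pairs=50, seed=22
        )

    def test_discordance_grows_with_insertion_density(self, small_library):
        genome = random_genome(40_000, seed=23)
        _, t1 = implant_insertions(genome, small_library, [(20_000, "ltrA")])
        _, t3 = implant_insertions(
            genome, small_library,
            [(10_000, "ltrA"), (20_000, "ltrB"), (30_000, "ltrA")],
        )
        n1 = len(find_discordant(to_mate_pairs(
            paired_reads(genome, t1, n_pairs=2000, seed=24))))
        n3 = len(find_discordant(to_mate_pairs(
            paired_reads(genome, t3, n_pairs=2000, seed=24))))
        assert n3 > n1 > 0

    def test_cluster_recovered_near_insertion(self, small_library):
        genome = random_genome(40_000, seed=25)
        _, truth = implant_insertions(genome, small_library, [(20_000, "ltrA")])
        pairs = paired_reads(genome, truth, n_pairs=8000, seed=26)
        discordant = find_discordant(to_mate_pairs(pairs))
        clusters = cluster_pairs(discordant)
        best = max(clusters, key=lambda c: c.n_reads)
        assert best.te_family == "ltrA"
        assert abs(best.position - truth[0].insertion_point) <= 400

    def test_invalid_insert_size(self):
        with pytest.raises(ValueError):
            paired_reads("A" * 1000, n_pairs=1, read_len=125, insert_mean=200)
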