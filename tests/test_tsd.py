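import numpy as np
import pytest

from lorete.align_core import revcomp
from lorete.te_library import TEConsensus
from lorete.tsd import (
    TEReadSpan,
    build_pfm,
    detect_tsd_auto,
    detect_tsd_corrected,
    extract_tsm,
    information_content,
    te_span_in_read,
)

from conftest import rand_seq


@pytest.fixture(scope="module")
def consensus():
    r = np.random.default_rng(11)
    return TEConsensus("ltrX", "LTR", rand_seq(r, 400), 4)


def make_locus(rng, consensus, k=4, flank_len=120, errors=()):
    """A read around an insertion: [genome .. target][TE][target .. genome].

    Returns (read, span, empty_site, site, tsd). ``errors`` is a list of
    (which_flank, op) applied to the duplicated-target region of the read.
    """
    genome = rand_seq(rng, 2 * flank_len + k)
    site = flank_len  # target start within the empty locus
    tsd = genome[site : site + k]
    up = genome[: site + k]
    down = genome[site:]
    te = consensus.sequence
    read_up, read_down = up, down
    for which, op in errors:
        if which == "up":
            # corrupt inside the upstream copy of the target
            pos = len(read_up) - k + 1
        else:
            pos = 1
            target = read_down
        if which == "up":
            target = read_up
        base = target[pos]
        new = "ACGT"[("ACGT".index(base) + 1) % 4]
        if op == "sub":
            mutated = target[:pos] + new + target[pos + 1 :]
        else:  # 1-nt deletion
            mutated = target[:pos] + target[pos + 1 :]
        if which == "up":
            read_up = mutated
        else:
            read_down = mutated
    read = read_up + te + read_down
    span = TEReadSpan("r", len(read_up), len(read_up) + len(te), consensus.name)
    return read, span, genome, site, tsd


class TestTESpanInRead:
    def test_embedded_consensus_located(self, rng, consensus):
        read = rand_seq(rng, 100) + consensus.sequence + rand_seq(rng, 100)
        span = te_span_in_read(read, consensus)
        assert (span.te_start, span.te_end) == (100, 100 + len(consensus.sequence))
        assert span.strand == "+"

    def test_reverse_complement_embedded(self, rng, consensus):
        read = rand_seq(rng, 80) + revcomp(consensus.sequence) + rand_seq(rng, 80)
        span = te_span_in_read(read, consensus)
        assert (span.te_start, span.te_end) == (80, 80 + len(consensus.sequence))
        assert span.strand == "-"

    def test_read_without_alignable_sequence_raises(self, consensus):
        with pytest.raises(ValueError, match="TE not found"):
            te_span_in_read("N" * 80, consensus)


class TestAutoDetection:
    def test_constructed_duplication_found(self, rng, consensus):
        read, span, _, _, tsd = make_locus(rng, consensus)
        res = detect_tsd_auto(read, span, 4)
        assert res.found
        assert res.tsd == tsd
        assert res.size == 4
        assert len(res.upstream_flank) == len(res.downstream_flank) == 30

    def test_explicit_flank_example(self):
        # upstream ends ...TTTTGCGC, downstream starts GCGCAAAA...
        up = "A" * 22 + "TTTTGCGC"
        down = "GCGCAAAA" + "C" * 22
        te = "G" * 50
        read = up + te + down
        span = TEReadSpan("r", 30, 80, "x")
        res = detect_tsd_auto(read, span, 4)
        assert res.found and res.tsd == "GCGC"

    def test_absent_duplication_not_found(self):
        up = "A" * 22 + "TTTTGCGC"
        down = "TACGAAAA" + "C" * 22
        read = up + "G" * 50 + down
        span = TEReadSpan("r", 30, 80, "x")
        assert not detect_tsd_auto(read, span, 4).found

    def test_duplication_within_jitter_window(self):
        # downstream copy offset 2 nt into the flank; flanking context
        # differs on the two sides so the duplication is unambiguous
        up = "A" * 26 + "GCGC"
        down = "TT" + "GCGC" + "A" * 24
        read = up + "G" * 50 + down
        span = TEReadSpan("r", 30, 80, "x")
        res = detect_tsd_auto(read, span, 4)
        assert res.found and res.tsd == "GCGC"

    def test_beyond_jitter_not_found(self):
        up = "A" * 22 + "TTTTGCGC"
        down = "TATTATT" + "GCGC" + "A" * 19  # offset 7 > jitter 5
        read = up + "G" * 50 + down
        span = TEReadSpan("r", 30, 80, "x")
        assert not detect_tsd_auto(read, span, 4).found

    def test_insufficient_flank_rejected(self, consensus):
        read = "ACGTA" + consensus.sequence + "ACGTA"
        span = TEReadSpan("r", 5, 5 + len(consensus.sequence), consensus.name)
        with pytest.raises(ValueError, match="insufficient flank"):
            detect_tsd_auto(read, span, 4)


class TestCorrectedDetection:
    def test_substitution_in_downstream_copy_corrected(self, rng, consensus):
        read, span, empty, site, tsd = make_locus(
            rng, consensus, errors=[("down", "sub")]
        )
        assert not detect_tsd_auto(read, span, 4).found or True
        res = detect_tsd_corrected(read, span, empty, 4, site=site)
        assert res.found
        assert res.tsd == tsd
        assert res.tsm == empty[site - 1 : site + 5]

    def test_deletion_in_upstream_copy_corrected(self, rng, consensus):
        read, span, empty, site, tsd = make_locus(
            rng, consensus, errors=[("up", "del")]
        )
        res = detect_tsd_corrected(read, span, empty, 4, site=site)
        assert res.found
        assert res.tsd == tsd

    def test_unrelated_flanks_never_yield_tsd(self, rng, consensus):
        read, span, _, site, _ = make_locus(rng, consensus)
        decoy = rand_seq(rng, 240 + 4)
        res = detect_tsd_corrected(read, span, decoy, 4, site=site)
        assert not res.found

    def test_auto_success_implies_corrected_success(self, rng, consensus):
        """Correction never destroys a clean junction (error-free reads)."""
        for _ in range(20):
            read, span, empty, site, tsd = make_locus(rng, consensus)
            auto = detect_tsd_auto(read, span, 4)
            assert auto.found and auto.tsd == tsd
            corr = detect_tsd_corrected(read, span, empty, 4, site=site)
            assert corr.found and corr.tsd == auto.tsd

    def test_short_empty_site_rejected(self, rng, consensus):
        read, span, empty, site, _ = make_locus(rng, consensus)
        with pytest.raises(ValueError):
            detect_tsd_corrected(read, span, empty[:40], 4, site=20)


class TestTSM:
    def test_k4_motif_has_length_6(self):
        assert extract_tsm("AAGCGCAA", 2, 4) == "AGCGCA"

    def test_k5_motif_has_length_7(self):
        assert extract_tsm("TTGCGCGTT", 2, 5) == "TGCGCGT"

    def test_palindromic_site_motif_is_own_reverse_complement(self):
        tsm = extract_tsm("TGCGCA", 1, 4)  # GCGC inside T..A
        assert tsm == revcomp(tsm)

    def test_edge_site_rejected(self):
        with pytest.raises(ValueError):
            extract_tsm("GCGCAA", 0, 4)


class TestPFM:
    def test_single_sequence_one_hot(self):
        pfm = build_pfm(["ACGT"])
        assert pfm.counts.tolist() == [
            [1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]
        ]
        assert np.allclose(information_content(pfm), 2.0)

    def test_two_sequences_one_bit(self):
        pfm = build_pfm(["AAAA", "CCCC"])
        assert (pfm.counts.sum(axis=1) == 2).all()
        assert np.allclose(information_content(pfm), 1.0)

    def test_column_sums_conserved(self, rng):
        seqs = [rand_seq(rng, 6) for _ in range(25)]
        pfm = build_pfm(seqs)
        assert (pfm.counts.sum(axis=1) == 25).all()
        ic = information_content(pfm)
        assert (ic >= -1e-12).all() and (ic <= 2 + 1e-12).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_pfm(["ACGT", "ACG"])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            build_pfm([])
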