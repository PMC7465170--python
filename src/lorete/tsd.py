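"""Target-site duplication (TSD) detection at single-read resolution.

LTR integration proceeds by staggered cuts, duplicating a short (here
4–5 nt) genomic target on both sides of the new provirus. A bona fide
insertion carried by a single long read therefore shows the same k-mer at
the end of its upstream flank and the start of its downstream flank. Auto
mode looks for that duplication directly in the read; corrected mode first
repairs sequencing errors in the two 30-nt flanks by aligning them to the
empty genomic target present in the assembly, and only accepts a
duplication that corresponds to one genomic k-mer spanning the empty
insertion site — the correction can repair a junction but cannot
manufacture one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

import edlib

from .align_core import local_align
from .te_library import TEConsensus

FLANK = 30
JITTER = 5
SEARCH_SLACK = 20


@dataclass(frozen=True)
class TEReadSpan:
    """The interval of a read covered by the TE alignment."""

    read_id: str
    te_start: int
    te_end: int
    family: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.te_start < self.te_end:
            raise ValueError("need 0 <= te_start < te_end")


@dataclass(frozen=True)
class TSDResult:
    """Outcome of junction analysis for one read."""

    mode: str  # auto | corrected
    found: bool
    tsd: str
    size: int
    tsm: str
    upstream_flank: str
    downstream_flank: str

    def __post_init__(self) -> None:
        if self.found and len(self.tsd) != self.size:
            raise ValueError("found TSD must have the expected size")
        if self.tsm and len(self.tsm) != self.size + 2:
            raise ValueError("TSM must be the TSD plus 1 nt of context each side")


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position ACGT counts over a set of equal-length sequences."""

    counts: np.ndarray  # shape (length, 4), columns A C G T
    n_sequences: int

    @property
    def length(self) -> int:
        return self.counts.shape[0]


def te_span_in_read(read_seq: str, consensus: TEConsensus) -> TEReadSpan:
    """Locate the TE within a read by best local alignment of the consensus.

    Raises ``ValueError`` ("TE not found in read") when no alignment scores
    above zero.
    """
    aln = local_align(
        consensus.sequence, read_seq, query_id=consensus.name, target_id="read"
    )
    if aln is None:
        raise ValueError("TE not found in read")
    return TEReadSpan(
        read_id="read",
        te_start=aln.target_interval[0],
        te_end=aln.target_interval[1],
        family=consensus.name,
        strand=aln.strand,
    )


def _flanks(read_seq: str, span: TEReadSpan, flank: int) -> tuple[str, str]:
    if span.te_start < flank or span.te_end + flank > len(read_seq):
        raise ValueError("insufficient flank")
    return (
        read_seq[span.te_start - flank : span.te_start],
        read_seq[span.te_end : span.te_end + flank],
    )


def _match_duplication(
    upstream: str, downstream: str, k: int, jitter: int
) -> tuple[str, int, int] | None:
    """Find a k-mer duplicated near both junctions.

    Returns ``(kmer, a, b)`` where the upstream copy ends ``a`` positions
    before the upstream flank's end and the downstream copy starts ``b``
    positions into the downstream flank; the junction-proximal match
    (smallest a + b, then most balanced) wins.
    """
    hits = []
    for a in range(jitter):
        if len(upstream) - a - k < 0:
            continue
        up_kmer = upstream[len(upstream) - a - k : len(upstream) - a]
        for b in range(jitter):
            if b + k > len(downstream):
                continue
            if up_kmer == downstream[b : b + k]:
                hits.append((a + b, max(a, b), a, b, up_kmer))
    if not hits:
        return None
    _, _, a, b, kmer = min(hits)
    return kmer, a, b


def detect_tsd_auto(
    read_seq: str,
    span: TEReadSpan,
    expected_size: int,
    *,
    flank: int = FLANK,
    jitter: int = JITTER,
) -> TSDResult:
    """Look for the expected-size duplication directly in the read flanks.

    A TSD is called when some k-mer ending within the last ``jitter``
    positions of the upstream flank equals a k-mer starting within the
    first ``jitter`` positions of the downstream flank.
    """
    upstream, downstream = _flanks(read_seq, span, flank)
    hit = _match_duplication(upstream, downstream, expected_size, jitter)
    return TSDResult(
        mode="auto",
        found=hit is not None,
        tsd=hit[0] if hit else "",
        size=expected_size,
        tsm="",
        upstream_flank=upstream,
        downstream_flank=downstream,
    )


def _locate_all(query: str, target: str) -> tuple[int, list[tuple[int, int]]]:
    """All best infix edit-distance placements of query within target."""
    res = edlib.align(query, target, mode="HW", task="locations")
    if res["editDistance"] < 0:
        return -1, []
    return res["editDistance"], [(s, e + 1) for s, e in res["locations"]]


def detect_tsd_corrected(
    read_seq: str,
    span: TEReadSpan,
    empty_site_seq: str,
    expected_size: int,
    *,
    site: int | None = None,
    flank: int = FLANK,
    slack: int = SEARCH_SLACK,
    max_flank_dist: int | None = None,
) -> TSDResult:
    """Error-corrected TSD detection against the empty genomic target.

    Each read flank is placed on the empty locus around the nominal
    insertion point ``site`` (defaults to the sequence midpoint) by
    minimum-edit-distance infix alignment and replaced by the genomic
    window it aligns to. At a bona fide junction the upstream window ends
    at the breakpoint and the downstream window starts one target-size
    earlier, so the two genomic windows overlap by exactly k nt — that
    overlap is the duplicated target. A TSD is reported only when a
    placement pair with this k-overlap geometry exists and both flanks
    match the locus well (edit distance at most ``max_flank_dist``,
    default flank/4 + 1); read flanks that do not correspond to the empty
    site therefore never yield a TSD, and the correction cannot
    manufacture a junction that the read does not support.
    """
    k = expected_size
    upstream, downstream = _flanks(read_seq, span, flank)
    if site is None:
        site = len(empty_site_seq) // 2
    if site < flank or site + flank > len(empty_site_seq):
        raise ValueError("empty_site_seq too short around the insertion point")
    if max_flank_dist is None:
        max_flank_dist = flank // 4 + 1

    miss = TSDResult(
        mode="corrected",
        found=False,
        tsd="",
        size=k,
        tsm="",
        upstream_flank=upstream,
        downstream_flank=downstream,
    )

    # Upstream flank ends at the breakpoint; downstream starts k before it.
    up_lo = max(0, site - flank - slack)
    up_hi = min(len(empty_site_seq), site + k + slack)
    d_up, up_locs = _locate_all(upstream, empty_site_seq[up_lo:up_hi])
    down_lo = max(0, site - k - slack)
    down_hi = min(len(empty_site_seq), site + flank + slack)
    d_down, down_locs = _locate_all(downstream, empty_site_seq[down_lo:down_hi])
    if d_up < 0 or d_down < 0 or d_up > max_flank_dist or d_down > max_flank_dist:
        return miss
    up_ends = sorted(
        {up_lo + e for _, e in up_locs if flank <= up_lo + e <= len(empty_site_seq)}
    )
    down_starts = sorted(
        {
            down_lo + s
            for s, _ in down_locs
            if down_lo + s + flank <= len(empty_site_seq)
        }
    )

    def down_anchored_dist(j: int) -> int:
        # downstream flank must start at j - k; its far end is free (SHW)
        target = empty_site_seq[j - k : j - k + flank + slack]
        return int(edlib.align(downstream, target, mode="SHW")["editDistance"])

    def up_anchored_dist(j: int) -> int:
        # upstream flank must end at j; anchor by reversing both sequences
        target = empty_site_seq[max(0, j - flank - slack) : j][::-1]
        return int(edlib.align(upstream[::-1], target, mode="SHW")["editDistance"])

    # candidate junctions: every placement either flank proposes; each is
    # validated by re-anchoring BOTH flanks there (the anchored fit must be
    # nearly as good as the free placement), then the best-supported,
    # most site-proximal junction wins
    candidates = {j for j in up_ends if j - k >= 0} | {
        ds + k for ds in down_starts if ds + k >= flank
    }
    best = None
    for j in sorted(candidates):
        if j - k + flank > len(empty_site_seq):
            continue
        du = up_anchored_dist(j)
        dd = down_anchored_dist(j)
        if du > min(d_up + 1, max_flank_dist) or dd > min(d_down + 1, max_flank_dist):
            continue
        key = (du + dd, abs(j - site), j)
        if best is None or key < best[0]:
            best = (key, j)
    if best is None:
        return miss
    junction = best[1]

    tsd = empty_site_seq[junction - k : junction]
    corr_up = empty_site_seq[junction - flank : junction]
    corr_down = empty_site_seq[junction - k : junction - k + flank]
    tsm = ""
    if junction - k >= 1 and junction + 1 <= len(empty_site_seq):
        tsm = extract_tsm(empty_site_seq, junction - k, k)
    return TSDResult(
        mode="corrected",
        found=True,
        tsd=tsd,
        size=k,
        tsm=tsm,
        upstream_flank=corr_up,
        downstream_flank=corr_down,
    )


def extract_tsm(empty_site_seq: str, tsd_site: int, k: int) -> str:
    """The (k+2)-nt target site motif: the target plus 1 nt of context."""
    if tsd_site < 1 or tsd_site + k + 1 > len(empty_site_seq):
        raise ValueError("target site at sequence edge; no context for TSM")
    return empty_site_seq[tsd_site - 1 : tsd_site + k + 1]


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def build_pfm(seqs: list[str]) -> PositionFrequencyMatrix:
    """Position frequency matrix of equal-length ACGT sequences."""
    if not seqs:
        raise ValueError("need at least one sequence")
    length = len(seqs[0])
    counts = np.zeros((length, 4), dtype=np.int64)
    for seq in seqs:
        if len(seq) != length:
            raise ValueError("sequences must all have the same length")
        for i, base in enumerate(seq.upper()):
            if base not in _BASE_INDEX:
                raise ValueError(f"non-ACGT base {base!r}")
            counts[i, _BASE_INDEX[base]] += 1
    return PositionFrequencyMatrix(counts=counts, n_sequences=len(seqs))


def information_content(pfm: PositionFrequencyMatrix) -> np.ndarray:
    """Per-position information content in bits (0..2), WebLogo-style."""
    freqs = pfm.counts / pfm.n_sequences
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    return 2.0 + plogp.sum(axis=1)
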