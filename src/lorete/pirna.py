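"""piRNA-cluster localization and piRNA read quantification.

Cluster loci are located in a new assembly via their flanking sequences
(typically flanking-gene sequences); putative piRNAs are small-RNA reads
longer than 23 nt that do not match any other known small RNA, mapped
retaining only unique best-stratum alignments with at most 2 mismatches
(bowtie ``--best -v 2 -m 1`` semantics, ungapped); abundance is reported in
fixed 1-kb windows after miRNA-count normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .align_core import encode, find_infix, revcomp

MIN_PIRNA_LEN_EXCLUSIVE = 23
MAX_MISMATCHES = 2
WINDOW = 1000
MIN_PRODUCER_READS = 500


@dataclass(frozen=True)
class ClusterInterval:
    """A piRNA cluster located on an assembly contig."""

    name: str
    contig: str
    start: int
    end: int
    localization_mode: str  # two_flanks | one_flank_plus_length

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("cluster interval must be non-empty")


@dataclass(frozen=True)
class WindowCount:
    """Normalized piRNA count in one genome-anchored window."""

    contig: str
    window_start: int
    count: float


def _best_flank_hit(flank: str, assembly: Mapping[str, str]):
    best = None
    for contig in sorted(assembly):
        hit = find_infix(flank, assembly[contig])
        if hit is None:
            continue
        s, e, strand, dist = hit
        if best is None or dist < best[0]:
            best = (dist, contig, s, e)
    return best


def locate_cluster(
    assembly: Mapping[str, str],
    flank_a: str,
    flank_b: str | None = None,
    *,
    fallback_length: int | None = None,
    name: str = "cluster",
) -> ClusterInterval:
    """Locate a cluster between its two flanking sequences.

    With both flanks found on one contig, the cluster spans from the inner
    end of the first hit to the inner start of the second (orientation
    agnostic — roles swap if flank_b precedes flank_a). With a single
    flank, the interval extends ``fallback_length`` nt from the flank's
    inner end.
    """
    if flank_b is None and fallback_length is None:
        raise ValueError("need a second flank or a fallback length")
    hit_a = _best_flank_hit(flank_a, assembly)
    if hit_a is None:
        raise ValueError("flank_a not found in assembly")
    if flank_b is None:
        _, contig, _, end_a = hit_a
        end = min(end_a + fallback_length, len(assembly[contig]))
        return ClusterInterval(
            name=name,
            contig=contig,
            start=end_a,
            end=end,
            localization_mode="one_flank_plus_length",
        )
    hit_b = _best_flank_hit(flank_b, assembly)
    if hit_b is None:
        raise ValueError("flank_b not found in assembly")
    if hit_a[1] != hit_b[1]:
        raise ValueError(
            f"flanks map to different contigs: {hit_a[1]!r} vs {hit_b[1]!r}"
        )
    contig = hit_a[1]
    first, second = sorted([hit_a, hit_b], key=lambda h: h[2])
    start, end = first[3], second[2]
    if end <= start:
        raise ValueError("flank hits overlap; no interval between them")
    return ClusterInterval(
        name=name, contig=contig, start=start, end=end, localization_mode="two_flanks"
    )


def _ungapped_hits(
    read_arr: np.ndarray, genome_arr: np.ndarray, max_mismatches: int
) -> tuple[np.ndarray, np.ndarray]:
    """Start positions and mismatch counts of ungapped occurrences."""
    n = len(read_arr)
    if n > len(genome_arr):
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    windows = sliding_window_view(genome_arr, n)
    mism = ((windows != read_arr) | (windows == 4) | (read_arr == 4)).sum(axis=1)
    keep = mism <= max_mismatches
    return np.nonzero(keep)[0], mism[keep]


def map_read(
    read: str,
    assembly: Mapping[str, str],
    *,
    max_mismatches: int = MAX_MISMATCHES,
    _cache: dict | None = None,
) -> list[tuple[str, int, str, int]]:
    """All ungapped occurrences of a read (both strands) with <= k mismatches.

    Returns ``(contig, start, strand, mismatches)`` tuples.
    """
    hits = []
    arrs = _cache if _cache is not None else {}
    for contig, seq in assembly.items():
        if contig not in arrs:
            arrs[contig] = encode(seq)
        genome_arr = arrs[contig]
        for strand, q in (("+", read), ("-", revcomp(read))):
            starts, mism = _ungapped_hits(encode(q), genome_arr, max_mismatches)
            hits.extend(
                (contig, int(s), strand, int(m)) for s, m in zip(starts, mism)
            )
    return hits


def filter_pirna_reads(
    reads: Iterable[str],
    exclusion_sets: Iterable[str],
    *,
    min_len_exclusive: int = MIN_PIRNA_LEN_EXCLUSIVE,
    max_mismatches: int = MAX_MISMATCHES,
) -> list[str]:
    """Keep putative piRNAs: longer than 23 nt, unmatched by known small RNAs.

    A read is excluded when it occurs end-to-end (ungapped, either strand,
    at most ``max_mismatches`` mismatches) in any exclusion sequence.
    """
    exclusion = {f"x{i}": seq for i, seq in enumerate(exclusion_sets)}
    cache: dict = {}
    kept = []
    for read in reads:
        if len(read) <= min_len_exclusive:
            continue
        if exclusion and map_read(
            read, exclusion, max_mismatches=max_mismatches, _cache=cache
        ):
            continue
        kept.append(read)
    return kept


def unique_map_counts(
    reads: Iterable[str],
    assembly: Mapping[str, str],
    *,
    max_mismatches: int = MAX_MISMATCHES,
) -> list[tuple[str, int]]:
    """Positions of reads with a unique best-stratum alignment.

    A read contributes one ``(contig, position)`` iff exactly one of its
    minimum-mismatch alignments exists within ``max_mismatches``.
    """
    cache: dict = {}
    positions = []
    for read in reads:
        hits = map_read(read, assembly, max_mismatches=max_mismatches, _cache=cache)
        if not hits:
            continue
        best = min(h[3] for h in hits)
        stratum = [h for h in hits if h[3] == best]
        if len(stratum) == 1:
            contig, start, _, _ = stratum[0]
            positions.append((contig, start))
    return positions


def window_counts(
    positions: Iterable[tuple[str, int]],
    *,
    window: int = WINDOW,
    normalizer: float = 1.0,
) -> list[WindowCount]:
    """Per-window piRNA counts scaled by ``normalizer``.

    Windows are genome-anchored, non-overlapping, of fixed size; a position
    falls in the window containing it.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    counts: dict[tuple[str, int], int] = {}
    for contig, pos in positions:
        key = (contig, (pos // window) * window)
        counts[key] = counts.get(key, 0) + 1
    return [
        WindowCount(contig=c, window_start=w, count=n * normalizer)
        for (c, w), n in sorted(counts.items())
    ]


def producers(
    region_counts: Mapping[str, int], *, min_reads: int = MIN_PRODUCER_READS
) -> dict[str, int]:
    """Regions with strictly more than ``min_reads`` raw reads."""
    return {name: n for name, n in region_counts.items() if n > min_reads}


def normalize_by_mirna(count: float, mirna_total: float, scale: float = 1e6) -> float:
    """Scale a raw count to reads per ``scale`` miRNA-mapped reads."""
    if mirna_total <= 0:
        raise ValueError("mirna_total must be positive")
    return count * scale / mirna_total
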