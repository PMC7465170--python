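"""Kimura 2-parameter divergence and the binomial trap-model test.

The K2P distance d = -1/2 ln((1-2P-Q) sqrt(1-2Q)) separates transition (P)
and transversion (Q) differences; averaged within a TE family it proxies
the age of the family's most recent transposition wave(s).

The trap model posits that a TE invasion ends when a copy lands in a piRNA
cluster; under the null of uniform insertion, the number of insertions
falling inside clusters is Binomial(n, p) with p the clusters' fraction of
the genome, tested one-tailed against the upper tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from intervaltree import IntervalTree
from scipy.stats import binom

from .align_core import PairwiseAlignment

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class KimuraEstimate:
    """Transition/transversion fractions and the derived K2P distance."""

    P: float
    Q: float
    d: float


@dataclass(frozen=True)
class TrapTestResult:
    """One-tailed binomial test of insertion enrichment in clusters."""

    n: int
    p: float
    k: int
    pvalue: float
    min_significant: int
    alpha: float = 0.05


def pairwise_PQ(seq_a: str, seq_b: str) -> tuple[float, float]:
    """Transition and transversion difference fractions of a gapped pair.

    Both strings must have equal length; columns where either character is
    not one of ACGT (gaps, N, ...) are excluded from the denominator.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    compared = transitions = transversions = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a not in "ACGT" or b not in "ACGT":
            continue
        compared += 1
        if a == b:
            continue
        same_class = (a in PURINES) == (b in PURINES)
        if same_class:
            transitions += 1
        else:
            transversions += 1
    if compared == 0:
        raise ValueError("no comparable columns")
    return transitions / compared, transversions / compared


def k2p_distance(P: float, Q: float) -> float:
    """Kimura (1980) two-parameter distance in substitutions per site."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError("distance undefined (saturated P/Q)")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def alignment_PQ(aln: PairwiseAlignment, query: str, target: str) -> tuple[float, float]:
    """P and Q over the aligned (gap-free) columns of a pairwise alignment."""
    qi, ti = aln.query_interval[0], aln.target_interval[0]
    compared = transitions = transversions = 0
    for kind, length in aln.ops:
        if kind in ("match", "mismatch"):
            for off in range(length):
                a, b = query[qi + off].upper(), target[ti + off].upper()
                if a in "ACGT" and b in "ACGT" and a != b:
                    if (a in PURINES) == (b in PURINES):
                        transitions += 1
                    else:
                        transversions += 1
                if a in "ACGT" and b in "ACGT":
                    compared += 1
            qi += length
            ti += length
        elif kind == "insertion":
            qi += length
        else:
            ti += length
    if compared == 0:
        raise ValueError("no comparable columns")
    return transitions / compared, transversions / compared


def family_divergence(
    pairs: list[tuple[str, str]],
) -> tuple[float, int]:
    """Average K2P distance over copy-vs-consensus aligned pairs.

    ``pairs`` holds equal-length gapped strings (copy, consensus). Copies
    whose distance is undefined (saturation) are excluded; the count of
    exclusions is returned alongside the mean.
    """
    distances = []
    skipped = 0
    for a, b in pairs:
        try:
            distances.append(k2p_distance(*pairwise_PQ(a, b)))
        except ValueError:
            skipped += 1
    if not distances:
        raise ValueError("all copies saturated; family divergence undefined")
    return sum(distances) / len(distances), skipped


def family_divergence_from_copies(
    copies: list[str], consensus: str
) -> tuple[float, int]:
    """Average K2P distance of unaligned copies against their consensus.

    Each copy is globally aligned to the consensus (minimum edit distance)
    and P/Q are counted over the substitution columns; saturated copies are
    excluded and counted.
    """
    from .align_core import global_edit_align

    distances = []
    skipped = 0
    for copy in copies:
        aln = global_edit_align(copy, consensus)
        try:
            distances.append(k2p_distance(*alignment_PQ(aln, copy, consensus)))
        except ValueError:
            skipped += 1
    if not distances:
        raise ValueError("all copies saturated; family divergence undefined")
    return sum(distances) / len(distances), skipped


def binom_tail(n: int, p: float, k: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Binomial(n, p)."""
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return float(binom.sf(k - 1, n, p))


def min_significant(n: int, p: float, alpha: float = 0.05) -> int:
    """Smallest observed count rejecting the one-tailed null at ``alpha``.

    Returns ``n + 1`` when even k = n fails to reject (unreachable).
    """
    for k in range(n + 1):
        if binom_tail(n, p, k) < alpha:
            return k
    return n + 1


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted, disjoint list."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if end <= start:
            raise ValueError(f"empty or inverted interval ({start}, {end})")
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def trap_test(
    calls: list[int],
    clusters: list[tuple[int, int]],
    genome_length: int,
    alpha: float = 0.05,
) -> TrapTestResult:
    """Binomial trap-model test of insertion enrichment in piRNA clusters.

    ``calls`` are insertion-point coordinates, ``clusters`` half-open
    intervals on the same single coordinate system (overlaps are merged
    before computing p = cluster fraction of the genome).
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    merged = merge_intervals(clusters) if clusters else []
    cluster_span = sum(e - s for s, e in merged)
    if cluster_span > genome_length:
        raise ValueError("clusters exceed genome length")
    p = cluster_span / genome_length
    tree = IntervalTree.from_tuples(merged) if merged else IntervalTree()
    n = len(calls)
    k = sum(1 for pos in calls if tree.overlaps_point(pos))
    pvalue = binom_tail(n, p, k) if n > 0 else 1.0
    return TrapTestResult(
        n=n,
        p=p,
        k=k,
        pvalue=pvalue,
        min_significant=min_significant(n, p, alpha) if n > 0 else 1,
        alpha=alpha,
    )
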