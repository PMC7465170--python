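"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — full dynamic-programming tables,
transitive-closure clustering, per-base interval membership, pmf
enumeration — and shares no code with the package's own algorithms.
"""

from __future__ import annotations

import math

NEG = -(10**9)


def sw_affine_score(q: str, t: str, match=2, mismatch=-3, gap_open=-5, gap_extend=-2):
    """Best local alignment score, full Gotoh tables, single strand.

    A gap of length L costs gap_open + L * gap_extend.
    """
    n, m = len(q), len(t)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open + gap_extend, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open + gap_extend, F[i - 1][j] + gap_extend)
            s = match if q[i - 1] == t[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


_COMP = str.maketrans("ACGTN", "TGCAN")


def sw_affine_score_both_strands(q: str, t: str, **kw) -> int:
    rc = q.translate(_COMP)[::-1]
    return max(sw_affine_score(q, t, **kw), sw_affine_score(rc, t, **kw))


def levenshtein(a: str, b: str) -> int:
    """Classic full-table edit distance."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return prev[m]


def cluster_transitive_closure(positions: list[int], max_gap: int) -> list[list[int]]:
    """Clusters = connected components of the |pi - pj| <= max_gap graph."""
    n = len(positions)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= max_gap:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(positions[i])
    return sorted(sorted(g) for g in groups.values())


def binom_upper_tail(n: int, p: float, k: int) -> float:
    """P(X >= k) by direct pmf summation."""
    return sum(
        math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
    )


def interval_fraction_and_membership(
    intervals: list[tuple[int, int]], genome_length: int, points: list[int]
):
    """Per-base union fraction and point membership, by brute force."""
    covered = bytearray(genome_length)
    for s, e in intervals:
        for i in range(s, e):
            covered[i] = 1
    frac = sum(covered) / genome_length
    inside = sum(1 for p in points if 0 <= p < genome_length and covered[p])
    return frac, inside
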