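"""Pairwise alignment primitives.

Local alignment is an affine-gap Smith–Waterman (Gotoh) with BLASTN-like
scoring, searching both strands; it backs TE classification, MIV validation
and TE-end mapping within reads. Global alignment is a minimum-edit-distance
end-to-end alignment (edlib) used for flank error correction.

Coordinates are 0-based half-open throughout. A gap of length L costs
``gap_open + L * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from numba import njit

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: op kind -> (consumes query, consumes target)
OP_CONSUMES = {
    "match": (True, True),
    "mismatch": (True, True),
    "insertion": (True, False),
    "deletion": (False, True),
}


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScoringScheme:
    """BLASTN-like affine scoring; all penalties are negative numbers."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


DEFAULT_SCORING = ScoringScheme()


@dataclass
class PairwiseAlignment:
    """One pairwise alignment between a query and a target sequence.

    ``ops`` is an ordered list of ``(kind, length)`` with kind in
    {match, mismatch, insertion, deletion}; insertion consumes query only,
    deletion consumes target only. ``query_interval`` always refers to
    forward-strand query coordinates; for strand ``-`` it is the interval
    whose reverse complement aligns to ``target_interval``.
    """

    query_id: str
    target_id: str
    query_interval: tuple[int, int]
    target_interval: tuple[int, int]
    strand: str
    ops: list[tuple[str, int]]
    n_matches: int
    n_columns: int
    score: float

    def __post_init__(self) -> None:
        qlen = sum(l for k, l in self.ops if OP_CONSUMES[k][0])
        tlen = sum(l for k, l in self.ops if OP_CONSUMES[k][1])
        if qlen != self.query_interval[1] - self.query_interval[0]:
            raise ValueError("ops do not cover the query interval")
        if tlen != self.target_interval[1] - self.target_interval[0]:
            raise ValueError("ops do not cover the target interval")
        if self.n_matches > self.n_columns:
            raise ValueError("n_matches exceeds aligned columns")

    def to_tsv_row(self) -> str:
        """PAF-like tab-separated representation."""
        cig = "".join(f"{l}{k[0].upper()}" for k, l in self.ops)
        return "\t".join(
            str(x)
            for x in (
                self.query_id,
                *self.query_interval,
                self.strand,
                self.target_id,
                *self.target_interval,
                self.n_matches,
                self.n_columns,
                self.score,
                cig,
            )
        )


_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Map ACGT to 0..3 and anything else (incl. N) to 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_NEG = -(10**8)


@njit(cache=True)
def _sw_fill(q, t, match, mismatch, gap_open, gap_extend):
    """Gotoh local alignment fill.

    Returns (traceback matrix, best score, best-cell rows, best-cell cols).
    Traceback byte: bits 0-1 = H source (0 stop, 1 diag, 2 target-gap,
    3 query-gap); bit 2 = target-gap extends; bit 3 = query-gap extends.
    """
    n, m = len(q), len(t)
    tb = np.zeros((n + 1, m + 1), dtype=np.uint8)
    h_prev = np.zeros(m + 1, dtype=np.int64)
    h_cur = np.zeros(m + 1, dtype=np.int64)
    f_col = np.full(m + 1, _NEG, dtype=np.int64)
    best = 0
    cap = 64
    bi = np.zeros(cap, dtype=np.int64)
    bj = np.zeros(cap, dtype=np.int64)
    nbest = 0
    for i in range(1, n + 1):
        e = _NEG
        h_cur[0] = 0
        qi = q[i - 1]
        for j in range(1, m + 1):
            e_open = h_cur[j - 1] + gap_open + gap_extend
            e_ext = e + gap_extend
            if e_ext > e_open:
                e = e_ext
                ebit = 4
            else:
                e = e_open
                ebit = 0
            f_open = h_prev[j] + gap_open + gap_extend
            f_ext = f_col[j] + gap_extend
            if f_ext > f_open:
                f_col[j] = f_ext
                fbit = 8
            else:
                f_col[j] = f_open
                fbit = 0
            tj = t[j - 1]
            s = match if (qi == tj and qi < 4) else mismatch
            h = 0
            choice = 0
            d = h_prev[j - 1] + s
            if d > h:
                h = d
                choice = 1
            if e > h:
                h = e
                choice = 2
            if f_col[j] > h:
                h = f_col[j]
                choice = 3
            h_cur[j] = h
            tb[i, j] = choice + ebit + fbit
            if h > best:
                best = h
                nbest = 1
                bi[0] = i
                bj[0] = j
            elif h == best and h > 0 and nbest < cap:
                bi[nbest] = i
                bj[nbest] = j
                nbest += 1
        h_prev, h_cur = h_cur, h_prev
    return tb, best, bi[:nbest], bj[:nbest]


def _traceback(tb, q, t, i, j):
    """Walk the traceback from cell (i, j); return (qs, ts, ops)."""
    ops: list[tuple[str, int]] = []

    def push(kind):
        if ops and ops[-1][0] == kind:
            ops[-1] = (kind, ops[-1][1] + 1)
        else:
            ops.append((kind, 1))

    state = "H"
    while True:
        byte = tb[i, j]
        if state == "H":
            choice = byte & 3
            if choice == 0:
                break
            if choice == 1:
                push("match" if (q[i - 1] == t[j - 1] and q[i - 1] < 4) else "mismatch")
                i -= 1
                j -= 1
            elif choice == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # gap consuming target
            push("deletion")
            if not byte & 4:
                state = "H"
            j -= 1
        else:  # gap consuming query
            push("insertion")
            if not byte & 8:
                state = "H"
            i -= 1
    ops.reverse()
    return i, j, ops


def _best_local(q_arr, t_arr, scoring):
    tb, best, bis, bjs = _sw_fill(
        q_arr,
        t_arr,
        scoring.match,
        scoring.mismatch,
        scoring.gap_open,
        scoring.gap_extend,
    )
    if best <= 0:
        return None
    picked = None
    for i, j in zip(bis, bjs):
        qs, ts, ops = _traceback(tb, q_arr, t_arr, int(i), int(j))
        span = int(j) - ts
        key = (span, -ts)  # longest target span, then leftmost target start
        if picked is None or key > picked[0]:
            picked = (key, qs, int(i), ts, int(j), ops)
    _, qs, qe, ts, te, ops = picked
    return best, qs, qe, ts, te, ops


def local_align(
    query: str,
    target: str,
    scoring: ScoringScheme = DEFAULT_SCORING,
    *,
    query_id: str = "query",
    target_id: str = "target",
    both_strands: bool = True,
) -> PairwiseAlignment | None:
    """Maximum-scoring local alignment of ``query`` against ``target``.

    Searches both strands (unless ``both_strands`` is false); ties between
    strands go to ``+``. Returns ``None`` when no alignment scores above 0
    ("no hit").

    Raises
    ------
    ValueError
        If either sequence is empty.
    """
    if not query or not target:
        raise ValueError("cannot align empty sequences")
    t_arr = encode(target)
    fwd = _best_local(encode(query), t_arr, scoring)
    rev = (
        _best_local(encode(revcomp(query)), t_arr, scoring) if both_strands else None
    )
    if fwd is None and rev is None:
        return None
    use_rev = rev is not None and (fwd is None or rev[0] > fwd[0])
    best, qs, qe, ts, te, ops = rev if use_rev else fwd
    strand = "-" if use_rev else "+"
    if use_rev:  # map interval back to forward query coordinates
        qs, qe = len(query) - qe, len(query) - qs
    n_matches = sum(l for k, l in ops if k == "match")
    n_columns = sum(l for _, l in ops)
    return PairwiseAlignment(
        query_id=query_id,
        target_id=target_id,
        query_interval=(qs, qe),
        target_interval=(ts, te),
        strand=strand,
        ops=ops,
        n_matches=n_matches,
        n_columns=n_columns,
        score=float(best),
    )


def percent_identity(aln: PairwiseAlignment) -> float:
    """100 * matches / aligned columns (gap columns included)."""
    if aln.n_columns == 0:
        raise ValueError("alignment has no columns")
    return 100.0 * aln.n_matches / aln.n_columns


def target_coverage(aln: PairwiseAlignment, target_len: int) -> float:
    """Fraction of the target covered by the aligned target interval."""
    if target_len <= 0:
        raise ValueError("target_len must be positive")
    span = aln.target_interval[1] - aln.target_interval[0]
    if target_len < span:
        raise ValueError("target_len shorter than aligned span")
    return span / target_len


_EDLIB_OP = {"=": "match", "X": "mismatch", "I": "insertion", "D": "deletion"}


def _cigar_ops(cigar: str) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            kind = _EDLIB_OP[ch]
            if ops and ops[-1][0] == kind:
                ops[-1] = (kind, ops[-1][1] + int(num))
            else:
                ops.append((kind, int(num)))
            num = ""
    return ops


def global_edit_align(
    a: str, b: str, *, query_id: str = "a", target_id: str = "b"
) -> PairwiseAlignment:
    """Minimum-edit-distance end-to-end alignment of ``a`` to ``b``.

    The score is the negated Levenshtein distance.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    res = edlib.align(a, b, task="path", mode="NW")
    ops = _cigar_ops(res["cigar"])
    n_matches = sum(l for k, l in ops if k == "match")
    return PairwiseAlignment(
        query_id=query_id,
        target_id=target_id,
        query_interval=(0, len(a)),
        target_interval=(0, len(b)),
        strand="+",
        ops=ops,
        n_matches=n_matches,
        n_columns=sum(l for _, l in ops),
        score=-float(res["editDistance"]),
    )


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance between two strings."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    return int(edlib.align(a, b, mode="NW")["editDistance"])


def find_infix(
    query: str, target: str, *, max_distance: int = -1, both_strands: bool = True
) -> tuple[int, int, str, int] | None:
    """Best approximate occurrence of ``query`` inside ``target``.

    Infix (semi-global) edit-distance search; returns
    ``(start, end, strand, distance)`` on the forward target, or ``None``
    when no occurrence within ``max_distance`` exists (-1 = unbounded).
    Ties go to the forward strand, then the leftmost location.
    """
    if not query or not target:
        raise ValueError("cannot align empty sequences")
    hits = []
    for strand, q in (("+", query), ("-", revcomp(query))):
        res = edlib.align(q, target, mode="HW", task="locations", k=max_distance)
        if res["editDistance"] >= 0:
            s, e = res["locations"][0]
            hits.append((res["editDistance"], strand == "-", s, (s, e + 1, strand)))
    if not hits:
        return None
    dist, _, _, (s, e, strand) = min(hits)
    return s, e, strand, dist
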