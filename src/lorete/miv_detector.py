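"""Minor insertional variant (MIV) detection for LTR retrotransposons.

MIVs are insertions present at low population frequency — down to a single
molecule — and therefore absent from the sample's own de novo assembly.
They are mined as large CIGAR insertion operations from long reads mapped
back to that assembly, merged across supporting reads, and validated
against the LTR consensus subset: more than 94% identity over at least 90%
of the consensus length, with the variant allowed to exceed the consensus
by at most 18 nt (the largest target-site duplication reported for any LTR
element).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

from .global_variants import best_hit
from .align_core import percent_identity, target_coverage
from .te_library import TELibrary

MIN_CANDIDATE_LEN = 1000  # strictly longer than this
MIN_IDENTITY = 94.0  # strictly more
MIN_COVERAGE = 0.90  # at least
TSD_ALLOWANCE = 18  # at most this many nt longer than the consensus
MERGE_WINDOW = 100
MERGE_LEN_RATIO = 0.8


@dataclass(frozen=True)
class InsertionCandidate:
    """A merged per-read insertion event on assembly coordinates.

    ``read_events`` records, per supporting read, where the inserted
    sequence starts within that read and how long it is — needed later to
    anchor TSD analysis on the right copy when a read contains several
    copies of a family.
    """

    contig: str
    position: int
    length: int
    sequence: str
    read_events: tuple[tuple[str, int, int], ...]  # (read_id, q_start, length)

    def __post_init__(self) -> None:
        if len(self.sequence) != self.length:
            raise ValueError("length must equal sequence length")
        if not self.read_events:
            raise ValueError("candidate needs at least one supporting read")

    @property
    def read_ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _, _ in self.read_events)

    @property
    def support(self) -> int:
        return len(self.read_events)


@dataclass(frozen=True)
class MIVCall:
    """An insertion candidate validated against the LTR library."""

    candidate: InsertionCandidate
    family: str
    identity: float
    consensus_coverage: float
    length_excess: int
    accepted: bool


def miv_passes(
    identity: float,
    coverage: float,
    length_excess: int,
    *,
    min_identity: float = MIN_IDENTITY,
    min_coverage: float = MIN_COVERAGE,
    tsd_allowance: int = TSD_ALLOWANCE,
) -> bool:
    """The MIV validation rule.

    Strict on identity (> 94%), inclusive on coverage (>= 90% of the
    consensus) and on the length excess (<= 18 nt beyond the consensus).
    """
    return (
        identity > min_identity
        and coverage >= min_coverage
        and length_excess <= tsd_allowance
    )


def _events_from_alignment(
    aln: pysam.AlignedSegment, min_len: int
) -> list[tuple[str, int, str, str, int]]:
    events = []
    query = aln.query_sequence
    ref_pos = aln.reference_start
    q_pos = 0
    for op, length in aln.cigartuples or []:
        if op == 1 and length > min_len:  # I
            if query is None:
                raise ValueError(f"alignment {aln.query_name} lacks sequence")
            events.append(
                (
                    aln.reference_name,
                    ref_pos,
                    query[q_pos : q_pos + length],
                    aln.query_name,
                    q_pos,
                )
            )
        if op in (0, 2, 3, 7, 8):
            ref_pos += length
        if op in (0, 1, 4, 7, 8):
            q_pos += length
    return events


def candidates_from_reads(
    read_alignments: Iterable[pysam.AlignedSegment],
    *,
    min_len: int = MIN_CANDIDATE_LEN,
    merge_window: int = MERGE_WINDOW,
    min_len_ratio: float = MERGE_LEN_RATIO,
) -> list[InsertionCandidate]:
    """Mine insertion candidates from long-read-vs-assembly alignments.

    Each CIGAR insertion strictly longer than ``min_len`` gives a per-read
    event; events on the same contig within ``merge_window`` nt whose
    lengths agree within ``min_len_ratio`` merge into one candidate. The
    candidate keeps the longest supporting sequence and the rounded mean
    position.
    """
    events: list[tuple[str, int, str, str]] = []
    for aln in read_alignments:
        if aln.is_unmapped or aln.cigartuples is None:
            continue
        events.extend(_events_from_alignment(aln, min_len))

    by_contig: dict[str, list[tuple[int, str, str, int]]] = {}
    for contig, pos, seq, rid, qpos in events:
        by_contig.setdefault(contig, []).append((pos, seq, rid, qpos))

    candidates = []
    for contig in sorted(by_contig):
        # open clusters: [positions, min_len, max_len, members]
        clusters: list[dict] = []
        for pos, seq, rid, qpos in sorted(by_contig[contig], key=lambda e: e[0]):
            placed = False
            for cl in clusters:
                if pos - cl["positions"][-1] > merge_window:
                    continue
                lo = min(cl["min_len"], len(seq))
                hi = max(cl["max_len"], len(seq))
                if lo / hi < min_len_ratio:
                    continue
                cl["positions"].append(pos)
                cl["min_len"] = lo
                cl["max_len"] = hi
                cl["members"].append((seq, rid, qpos))
                placed = True
                break
            if not placed:
                clusters.append(
                    {
                        "positions": [pos],
                        "min_len": len(seq),
                        "max_len": len(seq),
                        "members": [(seq, rid, qpos)],
                    }
                )
        for cl in clusters:
            longest = max(cl["members"], key=lambda m: len(m[0]))[0]
            candidates.append(
                InsertionCandidate(
                    contig=contig,
                    position=round(sum(cl["positions"]) / len(cl["positions"])),
                    length=len(longest),
                    sequence=longest,
                    read_events=tuple(
                        (rid, qpos, len(seq)) for seq, rid, qpos in cl["members"]
                    ),
                )
            )
    candidates.sort(key=lambda c: (c.contig, c.position))
    return candidates


def candidates_from_sam(
    sam_path: str | Path,
    *,
    min_len: int = MIN_CANDIDATE_LEN,
    merge_window: int = MERGE_WINDOW,
    min_len_ratio: float = MERGE_LEN_RATIO,
) -> list[InsertionCandidate]:
    """``candidates_from_reads`` over a SAM/BAM file."""
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        return candidates_from_reads(
            fh.fetch(until_eof=True),
            min_len=min_len,
            merge_window=merge_window,
            min_len_ratio=min_len_ratio,
        )


def validate_miv(
    candidate: InsertionCandidate,
    ltr_lib: TELibrary,
    *,
    min_identity: float = MIN_IDENTITY,
    min_coverage: float = MIN_COVERAGE,
    tsd_allowance: int = TSD_ALLOWANCE,
) -> MIVCall:
    """Validate a candidate against the LTR consensus subset."""
    entry, aln = best_hit(candidate.sequence, ltr_lib)
    if entry is None:
        return MIVCall(
            candidate=candidate,
            family="none",
            identity=0.0,
            consensus_coverage=0.0,
            length_excess=candidate.length,
            accepted=False,
        )
    identity = percent_identity(aln)
    coverage = target_coverage(aln, len(entry))
    excess = candidate.length - len(entry)
    return MIVCall(
        candidate=candidate,
        family=entry.name,
        identity=identity,
        consensus_coverage=coverage,
        length_excess=excess,
        accepted=miv_passes(
            identity,
            coverage,
            excess,
            min_identity=min_identity,
            min_coverage=min_coverage,
            tsd_allowance=tsd_allowance,
        ),
    )


def support_histogram(calls: Iterable[MIVCall]) -> dict[int, int]:
    """Histogram of supporting-read counts over accepted calls."""
    return dict(
        sorted(Counter(c.candidate.support for c in calls if c.accepted).items())
    )


def family_count_matrix(calls_per_sample: Mapping[str, Iterable[MIVCall]]) -> pd.DataFrame:
    """Accepted MIV counts per (sample, family)."""
    rows = [
        {"sample": sample, "family": c.family}
        for sample, calls in calls_per_sample.items()
        for c in calls
        if c.accepted
    ]
    if not rows:
        return pd.DataFrame(columns=["sample", "family", "count"])
    return (
        pd.DataFrame(rows)
        .groupby(["sample", "family"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
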