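"""Global TE variant calling from assembly-vs-reference alignments.

"Global" variants are insertions/deletions frequent enough in the sequenced
population to be incorporated in the de novo assembly; they are mined from
the CIGARs of assembly-to-reference alignments and classified against a TE
consensus library (best local hit; accepted when it covers more than 80% of
the consensus at more than 80% identity, both thresholds configurable down
to the unfiltered mode used for wild-type strains).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

from .align_core import local_align, percent_identity, target_coverage
from .te_library import TELibrary

MIN_SV_LEN = 50

# pysam cigar op codes that consume query / reference
_QUERY_OPS = {0, 1, 4, 7, 8}
_REF_OPS = {0, 2, 7, 8}


@dataclass(frozen=True)
class SVRecord:
    """An insertion or deletion structural variant on reference coordinates.

    For insertions ``end == start`` (the insertion point) and ``sequence``
    is the inserted assembly sequence; for deletions ``[start, end)`` spans
    the deleted reference segment, whose sequence is stored.
    """

    sample_id: str
    contig: str
    start: int
    end: int
    kind: str
    sequence: str

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"invalid SV kind {self.kind!r}")
        if self.end < self.start:
            raise ValueError("end < start")
        if self.kind == "insertion" and self.end != self.start:
            raise ValueError("insertion must have end == start")
        if not self.sequence:
            raise ValueError("SV sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GlobalTECall:
    """A structural variant classified against the TE library."""

    sv: SVRecord
    family: str
    identity: float
    consensus_coverage: float
    fragment_length: int
    accepted: bool


def extract_sv(
    alignments: Iterable[pysam.AlignedSegment],
    reference: Mapping[str, str],
    *,
    sample_id: str = "sample",
    min_sv_len: int = MIN_SV_LEN,
) -> list[SVRecord]:
    """Mine insertion/deletion SVs >= ``min_sv_len`` from alignment CIGARs.

    ``reference`` maps contig name to sequence and provides the deleted
    sequence for deletion records; inserted sequences come from the aligned
    query. Records without a CIGAR or sequence are skipped.
    """
    out: list[SVRecord] = []
    for aln in alignments:
        if aln.is_unmapped or aln.cigartuples is None:
            continue
        query = aln.query_sequence
        contig = aln.reference_name
        ref_seq = reference.get(contig)
        ref_pos = aln.reference_start
        q_pos = 0
        for op, length in aln.cigartuples:
            if op == 1 and length >= min_sv_len:  # I
                if query is None:
                    raise ValueError(f"alignment {aln.query_name} lacks sequence")
                out.append(
                    SVRecord(
                        sample_id=sample_id,
                        contig=contig,
                        start=ref_pos,
                        end=ref_pos,
                        kind="insertion",
                        sequence=query[q_pos : q_pos + length],
                    )
                )
            elif op == 2 and length >= min_sv_len:  # D
                if ref_seq is None:
                    raise ValueError(f"no reference sequence for contig {contig!r}")
                if ref_pos + length > len(ref_seq):
                    raise ValueError("CIGAR deletion beyond reference end")
                out.append(
                    SVRecord(
                        sample_id=sample_id,
                        contig=contig,
                        start=ref_pos,
                        end=ref_pos + length,
                        kind="deletion",
                        sequence=ref_seq[ref_pos : ref_pos + length],
                    )
                )
            if op in _REF_OPS:
                ref_pos += length
            if op in _QUERY_OPS:
                q_pos += length
        if ref_seq is not None and ref_pos > len(ref_seq):
            raise ValueError("CIGAR extends beyond reference end")
    out.sort(key=lambda r: (r.contig, r.start, r.kind))
    return out


def extract_sv_from_sam(
    sam_path: str | Path,
    reference: Mapping[str, str],
    *,
    sample_id: str = "sample",
    min_sv_len: int = MIN_SV_LEN,
) -> list[SVRecord]:
    """``extract_sv`` over a SAM/BAM file."""
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        return extract_sv(
            fh.fetch(until_eof=True),
            reference,
            sample_id=sample_id,
            min_sv_len=min_sv_len,
        )


def best_hit(sequence: str, lib: TELibrary):
    """Best local alignment of a sequence over all library entries.

    Ties on score go to the hit with the larger consensus coverage, then
    the lexicographically smallest family name. Returns ``(entry, aln)``
    or ``(None, None)`` when nothing scores above 0.
    """
    if len(lib) == 0:
        raise ValueError("empty TE library")
    picked: tuple | None = None
    for entry in lib:
        aln = local_align(sequence, entry.sequence, target_id=entry.name)
        if aln is None:
            continue
        cov = target_coverage(aln, len(entry))
        if picked is None:
            better = True
        else:
            p_score, p_cov, p_name = picked[0]
            if aln.score != p_score:
                better = aln.score > p_score
            elif cov != p_cov:
                better = cov > p_cov
            else:
                better = entry.name < p_name
        if better:
            picked = ((aln.score, cov, entry.name), entry, aln)
    if picked is None:
        return None, None
    return picked[1], picked[2]


def classify_sv(
    sv: SVRecord,
    lib: TELibrary,
    *,
    min_coverage: float = 0.80,
    min_identity: float = 80.0,
) -> GlobalTECall:
    """Classify an SV sequence against the TE library.

    Accepted iff the best hit covers strictly more than ``min_coverage`` of
    the consensus and is strictly more than ``min_identity`` percent
    identical; with both thresholds at 0 every best hit is accepted (the
    unfiltered wild-type mode).
    """
    entry, aln = best_hit(sv.sequence, lib)
    if entry is None:
        return GlobalTECall(
            sv=sv,
            family="none",
            identity=0.0,
            consensus_coverage=0.0,
            fragment_length=0,
            accepted=False,
        )
    identity = percent_identity(aln)
    coverage = target_coverage(aln, len(entry))
    fragment = aln.query_interval[1] - aln.query_interval[0]
    return GlobalTECall(
        sv=sv,
        family=entry.name,
        identity=identity,
        consensus_coverage=coverage,
        fragment_length=fragment,
        accepted=(coverage > min_coverage) and (identity > min_identity),
    )


def copy_table(calls: Iterable[GlobalTECall]) -> pd.DataFrame:
    """Accepted-insertion counts per (sample, family)."""
    rows = [
        {"sample": c.sv.sample_id, "family": c.family}
        for c in calls
        if c.accepted and c.sv.kind == "insertion"
    ]
    if not rows:
        return pd.DataFrame(columns=["sample", "family", "count"])
    return (
        pd.DataFrame(rows)
        .groupby(["sample", "family"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )


def shared_insertions(
    calls_a: list[GlobalTECall],
    calls_b: list[GlobalTECall],
    *,
    window: int = 100,
) -> int:
    """Count insertions shared between two samples.

    Accepted insertion calls of the same family on the same contig whose
    insertion points lie within +/- ``window`` are matched greedily by
    increasing distance, each call at most once.
    """
    a = [c for c in calls_a if c.accepted and c.sv.kind == "insertion"]
    b = [c for c in calls_b if c.accepted and c.sv.kind == "insertion"]
    candidates = []
    for i, ca in enumerate(a):
        for j, cb in enumerate(b):
            if ca.family != cb.family or ca.sv.contig != cb.sv.contig:
                continue
            dist = abs(ca.sv.start - cb.sv.start)
            if dist <= window:
                candidates.append((dist, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    shared = 0
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        shared += 1
    return shared
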