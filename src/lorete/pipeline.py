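"""End-to-end study simulation and stage runners.

Bundles the synthetic study conditions (a scaled-down genome carrying
fixed and minor LTR insertions with TSDs), runs the two detection
pipelines — global variants from the assembly-vs-reference alignment and
MIVs + TSDs from reads remapped to the assembly — and scores each stage
against the simulation truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from . import global_variants as gv
from . import miv_detector as miv
from . import simdata
from . import tsd as tsd_mod
from .te_library import TEConsensus, TELibrary, ltr_subset

CONTIG = "chr_sim"
MATCH_WINDOW = 100


def make_synthetic_library(
    seed=None,
    *,
    ltr_lengths: tuple[int, ...] = (1500, 1800, 2100),
    tsd_size: int = 4,
) -> TELibrary:
    """A small random TE library: three LTR families plus a LINE and a DNA
    transposon for classification contrast.

    LTR consensus lengths are scaled down (1.5–2.1 kb vs the 5–9 kb of
    real elements) so the stages run quickly; every LTR family makes a
    ``tsd_size``-nt duplication at integration.
    """
    rng = np.random.default_rng(seed)

    def rand_seq(n):
        return "".join(rng.choice(simdata.BASES, size=n))

    entries = [
        TEConsensus(
            name=f"simLTR{i + 1}",
            group="LTR",
            sequence=rand_seq(n),
            expected_tsd_size=tsd_size,
        )
        for i, n in enumerate(ltr_lengths)
    ]
    entries.append(
        TEConsensus(name="simLINE1", group="LINE", sequence=rand_seq(1200),
                    expected_tsd_size="unknown")
    )
    entries.append(
        TEConsensus(name="simDNA1", group="DNA", sequence=rand_seq(900),
                    expected_tsd_size=8)
    )
    return TELibrary(entries=entries, provenance=("synthetic",))


@dataclass
class SimStudy:
    """A simulated study: genomes, truth, reads and the library."""

    seed: int
    library: TELibrary
    reference: str
    assembly: str
    fixed_truth: list[simdata.SimInsertion]
    minor_truth: list[simdata.SimInsertion]
    reads: list[simdata.SimRead]
    params: dict = field(default_factory=dict)

    @property
    def read_seqs(self) -> dict[str, str]:
        return {r.name: r.sequence for r in self.reads}


def simulate_study(
    seed: int = 0,
    *,
    genome_length: int = 100_000,
    coverage: float = 30.0,
    error_rate: float = 0.0,
    n_fixed: int = 5,
    n_minor: int = 3,
    minor_frequency: float = 0.1,
    mean_read_len: int = 9000,
) -> SimStudy:
    """Generate the full synthetic study for the default conditions.

    A ``genome_length`` reference receives ``n_fixed`` fixed LTR
    insertions (present in the assembly) and the assembly then carries
    ``n_minor`` minor LTR insertions at ``minor_frequency``, seen only by
    the long reads.
    """
    rng = np.random.default_rng(seed)
    library = make_synthetic_library(rng.integers(2**31))
    reference = simdata.random_genome(
        genome_length, seed=int(rng.integers(2**31))
    )
    ltr_names = [e.name for e in ltr_subset(library)]

    def spaced_sites(length, n, margin):
        # evenly spaced anchors with jitter, far from ends and each other
        anchors = np.linspace(margin, length - margin, n + 2)[1:-1]
        jitter = rng.integers(-margin // 4, margin // 4 + 1, size=n)
        return sorted(int(a + j) for a, j in zip(anchors, jitter))

    fixed_sites = [
        (pos, ltr_names[i % len(ltr_names)])
        for i, pos in enumerate(spaced_sites(genome_length, n_fixed, 8000))
    ]
    assembly, fixed_truth = simdata.implant_insertions(
        reference, library, fixed_sites, contig=CONTIG
    )
    minor_positions = spaced_sites(len(assembly), n_minor, 12000)
    # implanted fixed loci in assembly coordinates (cumulative shift)
    fixed_spans = []
    shift = 0
    for t in sorted(fixed_truth, key=lambda t: t.site):
        start = t.insertion_point + shift
        fixed_spans.append((start, start + len(t.inserted_sequence)))
        shift += len(t.inserted_sequence)

    guard, min_sep = 3000, 5000
    minor_sites: list[tuple[int, str]] = []

    def clear(pos):
        ok_fixed = all(pos + guard < s or pos > e + guard for s, e in fixed_spans)
        ok_minor = all(abs(pos - p) >= min_sep for p, _ in minor_sites)
        return ok_fixed and ok_minor and pos + guard < len(assembly)

    for i, pos in enumerate(minor_positions):
        while not clear(pos):
            pos += 1000
        minor_sites.append((pos, ltr_names[i % len(ltr_names)]))
    minor_sites.sort()
    _, minor_truth = simdata.implant_insertions(
        assembly, library, minor_sites, contig=CONTIG, frequency=minor_frequency
    )
    profile = simdata.ErrorProfile.from_total(error_rate)
    reads = simdata.long_reads(
        assembly,
        minor_truth,
        coverage=coverage,
        mean_len=mean_read_len,
        profile=profile,
        contig=CONTIG,
        seed=int(rng.integers(2**31)),
    )
    return SimStudy(
        seed=seed,
        library=library,
        reference=reference,
        assembly=assembly,
        fixed_truth=fixed_truth,
        minor_truth=minor_truth,
        reads=reads,
        params=dict(
            genome_length=genome_length,
            coverage=coverage,
            error_rate=error_rate,
            n_fixed=n_fixed,
            n_minor=n_minor,
            minor_frequency=minor_frequency,
            mean_read_len=mean_read_len,
        ),
    )


def _read_header(study: SimStudy) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": CONTIG, "LN": len(study.assembly)}],
        }
    )


def run_global_stage(
    study: SimStudy, *, min_coverage: float = 0.80, min_identity: float = 80.0
) -> list[gv.GlobalTECall]:
    """Extract and classify SVs from the assembly-vs-reference alignment."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": CONTIG, "LN": len(study.reference)}],
        }
    )
    ordered = sorted(study.fixed_truth, key=lambda i: i.site)
    ops = []
    cursor = 0
    parts = []
    for ins in ordered:
        bp = ins.insertion_point
        ops.append((0, bp - cursor))
        parts.append(study.reference[cursor:bp])
        ops.append((1, len(ins.inserted_sequence)))
        parts.append(ins.inserted_sequence)
        cursor = bp
    ops.append((0, len(study.reference) - cursor))
    parts.append(study.reference[cursor:])
    seg = pysam.AlignedSegment(header)
    seg.query_name = "assembly"
    seg.query_sequence = "".join(parts)
    seg.reference_id = 0
    seg.reference_start = 0
    seg.cigartuples = ops
    svs = gv.extract_sv([seg], {CONTIG: study.reference}, sample_id="sim")
    return [
        gv.classify_sv(sv, study.library, min_coverage=min_coverage,
                       min_identity=min_identity)
        for sv in svs
    ]


def evaluate_global(study: SimStudy, calls: list[gv.GlobalTECall]) -> dict:
    """Recall/precision of accepted insertion calls against fixed truth."""
    accepted = [c for c in calls if c.accepted and c.sv.kind == "insertion"]
    matched = set()
    for truth in study.fixed_truth:
        for i, c in enumerate(accepted):
            if i in matched:
                continue
            if (
                c.family == truth.family
                and abs(c.sv.start - truth.insertion_point) <= MATCH_WINDOW
            ):
                matched.add(i)
                break
    n_true = len(study.fixed_truth)
    recall = len(matched) / n_true if n_true else 1.0
    precision = len(matched) / len(accepted) if accepted else 1.0
    return {
        "n_true": n_true,
        "n_accepted": len(accepted),
        "recall": recall,
        "precision": precision,
    }


def run_miv_stage(study: SimStudy) -> list[miv.MIVCall]:
    """Mine insertion candidates from the reads and validate against LTRs."""
    header = _read_header(study)
    segments = (r.to_aligned_segment(header) for r in study.reads)
    candidates = miv.candidates_from_reads(segments)
    ltr = ltr_subset(study.library)
    return [miv.validate_miv(c, ltr) for c in candidates]


def evaluate_miv(study: SimStudy, calls: list[miv.MIVCall]) -> dict:
    """Recall of accepted MIV calls against minor-insertion truth."""
    accepted = [c for c in calls if c.accepted]
    matched: dict[int, miv.MIVCall] = {}
    for t_idx, truth in enumerate(study.minor_truth):
        for c in accepted:
            if (
                c.family == truth.family
                and abs(c.candidate.position - truth.insertion_point)
                <= MATCH_WINDOW
            ):
                matched[t_idx] = c
                break
    n_true = len(study.minor_truth)
    return {
        "n_true": n_true,
        "n_accepted": len(accepted),
        "recall": len(matched) / n_true if n_true else 1.0,
        "min_support": min((c.candidate.support for c in accepted), default=0),
        "matched": matched,
    }


def run_tsd_stage(
    study: SimStudy,
    calls: list[miv.MIVCall],
    *,
    flank: int = tsd_mod.FLANK,
    window: int = 300,
) -> list[dict]:
    """Auto and corrected TSD detection for accepted MIV calls.

    For each accepted call the supporting reads are tried in order until
    one offers full flanks around the TE span (mirroring one-read-per-MIV
    inspection); the corrected mode uses the assembly sequence around the
    call position as the empty genomic target.
    """
    read_seqs = study.read_seqs
    results = []
    for call in calls:
        if not call.accepted:
            continue
        entry = study.library[call.family]
        k = entry.expected_tsd_size
        if k == "unknown":
            continue
        row: dict = {"call": call, "auto": None, "corrected": None}
        pos = call.candidate.position
        lo = max(0, pos - window)
        empty_site = study.assembly[lo : pos + window]
        site = pos - lo
        margin = flank + 100
        for read_id, q_start, q_len in call.candidate.read_events:
            seq = read_seqs[read_id]
            w_lo = max(0, q_start - margin)
            w_hi = min(len(seq), q_start + q_len + margin)
            try:
                # anchor the span search on this read's own insertion event
                # so other copies of the family elsewhere in the read cannot
                # capture the alignment
                span = tsd_mod.te_span_in_read(seq[w_lo:w_hi], entry)
                span = tsd_mod.TEReadSpan(
                    read_id=read_id,
                    te_start=w_lo + span.te_start,
                    te_end=w_lo + span.te_end,
                    family=span.family,
                    strand=span.strand,
                )
                row["auto"] = tsd_mod.detect_tsd_auto(seq, span, k, flank=flank)
                row["corrected"] = tsd_mod.detect_tsd_corrected(
                    seq, span, empty_site, k, site=site, flank=flank
                )
                row["read_id"] = read_id
                break
            except ValueError:
                continue
        results.append(row)
    return results


def evaluate_tsd(study: SimStudy, tsd_rows: list[dict], mode: str) -> dict:
    """Fraction of analyzed calls whose truth TSD was recovered exactly."""
    n = hit = 0
    for row in tsd_rows:
        call = row["call"]
        truth = next(
            (
                t
                for t in study.minor_truth
                if t.family == call.family
                and abs(call.candidate.position - t.insertion_point)
                <= MATCH_WINDOW
            ),
            None,
        )
        if truth is None or row[mode] is None:
            continue
        n += 1
        res = row[mode]
        if res.found and res.tsd == truth.tsd:
            hit += 1
    return {"n": n, "recall": hit / n if n else 0.0}
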