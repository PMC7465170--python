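"""Synthetic genomes, TE insertions and reads with known truth.

Every pipeline stage is testable without external data: a random genome
receives TE copies flanked by family-specific target-site duplications;
"fixed" insertions enter the assembly-like genome while "minor" insertions
are carried only by a stated fraction of read templates (too rare to be
assembled, the regime in which single-read detection operates); long reads
receive ONT-like substitution/indel errors and are emitted together with
their true alignments, so downstream callers consume ordinary SAM records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .align_core import revcomp
from .te_library import TELibrary

DEFAULT_GC = 0.42
BASES = np.array(list("ACGT"))

_CIGAR_CODE = {"M": 0, "I": 1, "D": 2, "S": 4}


@dataclass(frozen=True)
class ErrorProfile:
    """Per-base error probabilities for read simulation.

    The default ONT-like split of a total error rate is 40% substitutions,
    30% insertions, 30% deletions.
    """

    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0

    def __post_init__(self) -> None:
        rates = (self.substitution_rate, self.insertion_rate, self.deletion_rate)
        if any(not 0.0 <= r <= 0.2 for r in rates):
            raise ValueError("each error rate must lie in [0, 0.2]")
        if sum(rates) >= 0.5:
            raise ValueError("total error rate must be below 0.5")

    @classmethod
    def from_total(cls, total: float) -> "ErrorProfile":
        return cls(
            substitution_rate=0.4 * total,
            insertion_rate=0.3 * total,
            deletion_rate=0.3 * total,
        )

    @property
    def total(self) -> float:
        return self.substitution_rate + self.insertion_rate + self.deletion_rate


@dataclass(frozen=True)
class SimInsertion:
    """Truth for one implanted insertion.

    ``site`` is the 0-based start of the duplicated genomic target in the
    coordinates of the genome the insertion was implanted into; after
    implanting, the locus reads [target][TE][target]. ``frequency`` is 1.0
    for fixed insertions and the carrier fraction for minor ones.
    """

    contig: str
    site: int
    family: str
    tsd: str
    te_sequence: str
    frequency: float = 1.0

    @property
    def tsd_size(self) -> int:
        return len(self.tsd)

    @property
    def inserted_sequence(self) -> str:
        """The extra sequence relative to the empty haplotype (TE + TSD copy)."""
        return self.te_sequence + self.tsd

    @property
    def insertion_point(self) -> int:
        """Reference breakpoint (end of the original target) of the insertion."""
        return self.site + self.tsd_size


@dataclass(frozen=True)
class SimRead:
    """A simulated read and its true alignment to the source genome."""

    name: str
    sequence: str
    contig: str
    ref_start: int
    cigar: tuple[tuple[str, int], ...]
    carried_sites: tuple[int, ...] = ()

    def to_aligned_segment(self, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
        seg = pysam.AlignedSegment(header)
        seg.query_name = self.name
        seg.query_sequence = self.sequence
        seg.flag = 0
        seg.reference_id = header.get_tid(self.contig)
        seg.reference_start = self.ref_start
        seg.mapping_quality = 60
        seg.cigartuples = [(_CIGAR_CODE[op], ln) for op, ln in self.cigar]
        return seg


@dataclass(frozen=True)
class SimPair:
    """A simulated fragment's two mates with their truth classes.

    Each mate class is ``genome`` (fully outside any inserted segment),
    ``te`` (fully inside one), or ``junction`` (straddling a boundary).
    """

    name: str
    seq1: str
    seq2: str
    class1: str
    class2: str
    genome_pos1: tuple[str, int, str] | None
    genome_pos2: tuple[str, int, str] | None
    family1: str | None
    family2: str | None
    concordant: bool


def random_genome(length: int, gc: float = DEFAULT_GC, seed=None) -> str:
    """I.i.d. random genome with the given GC content."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(BASES, size=length, p=probs))


def implant_insertions(
    genome: str,
    lib: TELibrary,
    sites: Sequence[tuple[int, str]],
    *,
    contig: str = "chr_sim",
    frequency: float = 1.0,
) -> tuple[str, list[SimInsertion]]:
    """Implant TE copies with family-specific TSDs at the given sites.

    Each ``(position, family)`` site duplicates the k-nt genomic target so
    the final locus is [target][TE][target]. With ``frequency`` = 1.0 the
    modified genome is returned; minor insertions (frequency < 1) are only
    recorded in the truth — the returned genome is unchanged and the
    fraction applies to read templates drawn later.
    """
    if not 0.0 < frequency <= 1.0:
        raise ValueError("frequency must lie in (0, 1]")
    truth: list[SimInsertion] = []
    prev_end = None
    for pos, family in sorted(sites):
        entry = lib[family]
        k = entry.expected_tsd_size
        if k == "unknown":
            raise ValueError(f"family {family} has no expected TSD size")
        if pos < k or pos + k > len(genome) - k:
            raise ValueError(f"site {pos} too close to a contig end")
        if prev_end is not None and pos < prev_end:
            raise ValueError("overlapping insertion sites")
        prev_end = pos + k
        truth.append(
            SimInsertion(
                contig=contig,
                site=pos,
                family=family,
                tsd=genome[pos : pos + k],
                te_sequence=entry.sequence,
                frequency=frequency,
            )
        )
    if frequency < 1.0:
        return genome, truth
    out = []
    cursor = 0
    for ins in truth:
        # [target][TE][target]: emit up to the target's end, the TE, then
        # resume from the target's start so it appears a second time
        out.append(genome[cursor : ins.insertion_point])
        out.append(ins.te_sequence)
        cursor = ins.site
    out.append(genome[cursor:])
    modified = "".join(out)
    assert len(modified) == len(genome) + sum(
        len(i.inserted_sequence) for i in truth
    )
    return modified, truth


def _build_template(
    genome: str, carried: Sequence[SimInsertion]
) -> tuple[str, np.ndarray]:
    """Template string and per-base reference map (-1 for inserted bases)."""
    parts = []
    maps = []
    cursor = 0
    for ins in sorted(carried, key=lambda i: i.site):
        bp = ins.insertion_point
        parts.append(genome[cursor:bp])
        maps.append(np.arange(cursor, bp, dtype=np.int64))
        seg = ins.inserted_sequence
        parts.append(seg)
        maps.append(np.full(len(seg), -1, dtype=np.int64))
        cursor = bp
    parts.append(genome[cursor:])
    maps.append(np.arange(cursor, len(genome), dtype=np.int64))
    return "".join(parts), np.concatenate(maps)


def _ops_merge(ops: list[tuple[str, int]], op: str, n: int = 1) -> None:
    if n == 0:
        return
    if ops and ops[-1][0] == op:
        ops[-1] = (op, ops[-1][1] + n)
    else:
        ops.append((op, n))


def _simulate_read(
    template: str,
    refmap: np.ndarray,
    start: int,
    length: int,
    profile: ErrorProfile,
    rng: np.random.Generator,
) -> tuple[str, int, list[tuple[str, int]]] | None:
    """Apply errors to template[start:start+length]; return read + alignment."""
    seg = template[start : start + length]
    seg_map = refmap[start : start + length]
    p_del, p_sub, p_ins = (
        profile.deletion_rate,
        profile.substitution_rate,
        profile.insertion_rate,
    )
    u_del = rng.random(length)
    u_sub = rng.random(length)
    u_ins = rng.random(length)
    sub_bases = rng.choice(BASES, size=length)
    ins_bases = rng.choice(BASES, size=length)

    read_chars: list[str] = []
    ops: list[tuple[str, int]] = []
    prev_ref = None
    for i in range(length):
        mapped = seg_map[i] >= 0
        if mapped and prev_ref is not None and seg_map[i] > prev_ref + 1:
            _ops_merge(ops, "D", int(seg_map[i] - prev_ref - 1))
        if u_del[i] < p_del:
            if mapped:
                _ops_merge(ops, "D")
                prev_ref = int(seg_map[i])
            continue
        base = seg[i]
        if u_sub[i] < p_sub:
            base = str(sub_bases[i])
        read_chars.append(base)
        _ops_merge(ops, "M" if mapped else "I")
        if mapped:
            prev_ref = int(seg_map[i])
        if u_ins[i] < p_ins:
            read_chars.append(str(ins_bases[i]))
            _ops_merge(ops, "I")

    if not read_chars:
        return None
    # convert edge insertions to soft clips, drop edge deletions
    while ops and ops[0][0] == "D":
        ops.pop(0)
    while ops and ops[-1][0] == "D":
        ops.pop()
    if not any(op == "M" for op, _ in ops):
        return None
    if ops[0][0] == "I":
        ops[0] = ("S", ops[0][1])
    if ops[-1][0] == "I":
        ops[-1] = ("S", ops[-1][1])
    # leading deletions were dropped, so the alignment starts at the first
    # mapped template base that was not deleted
    first_m = None
    for i in range(length):
        if seg_map[i] >= 0 and not u_del[i] < p_del:
            first_m = int(seg_map[i])
            break
    if first_m is None:
        return None
    return "".join(read_chars), first_m, ops


def long_reads(
    genome: str,
    minor_insertions: Sequence[SimInsertion] = (),
    *,
    coverage: float = 30.0,
    mean_len: int = 9000,
    profile: ErrorProfile = ErrorProfile(),
    contig: str = "chr_sim",
    seed=None,
    min_len: int = 200,
    span_margin: int = 200,
) -> list[SimRead]:
    """ONT-like long reads over a genome plus optional minor insertions.

    Read starts are uniform, lengths gamma-distributed (shape 2) around
    ``mean_len``; errors follow ``profile``; reads are emitted until total
    bases reach ``coverage`` times the genome length.

    Minor insertions are carried by the designated fraction of the
    molecules that fully span their site (with ``span_margin`` nt of
    flanking genome on each side): for a frequency of 1/k, every k-th
    spanning molecule carries the insertion. Molecules that would only
    partially overlap a minor insertion are drawn from the empty
    haplotype.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    minors = sorted(minor_insertions, key=lambda i: i.site)
    every_kth = [max(1, round(1.0 / ins.frequency)) for ins in minors]
    span_counts = [0] * len(minors)
    templates: dict[tuple[int, ...], tuple[str, np.ndarray]] = {}
    target_bases = coverage * len(genome)
    total = 0
    reads: list[SimRead] = []
    idx = 0
    while total < target_bases:
        length = int(rng.gamma(shape=2.0, scale=mean_len / 2.0))
        length = max(min_len, min(length, len(genome)))
        start = int(rng.integers(0, len(genome) - length + 1))
        carried = []
        for i, ins in enumerate(minors):
            bp = ins.insertion_point
            spans = (
                start <= bp - span_margin
                and start + length >= bp + len(ins.inserted_sequence) + span_margin
            )
            if spans:
                span_counts[i] += 1
                if (span_counts[i] - 1) % every_kth[i] == 0:
                    carried.append(i)
        key = tuple(carried)
        if key not in templates:
            templates[key] = _build_template(genome, [minors[i] for i in carried])
        template, refmap = templates[key]
        sim = _simulate_read(template, refmap, start, length, profile, rng)
        if sim is None:
            continue
        seq, ref_start, ops = sim
        reads.append(
            SimRead(
                name=f"read{idx:06d}",
                sequence=seq,
                contig=contig,
                ref_start=ref_start,
                cigar=tuple(ops),
                carried_sites=tuple(minors[i].site for i in carried),
            )
        )
        total += len(seq)
        idx += 1
    return reads


def paired_reads(
    genome: str,
    insertions: Sequence[SimInsertion] = (),
    *,
    n_pairs: int = 1000,
    read_len: int = 125,
    insert_mean: int = 350,
    insert_sd: int = 30,
    profile: ErrorProfile = ErrorProfile(),
    contig: str = "chr_sim",
    seed=None,
) -> list[SimPair]:
    """Paired-end fragments from the genome carrying the given insertions.

    Mates are classified against the inserted segments: a pair straddling a
    TE produces one genome-side and one TE-side mate (the truth a mapper
    would recover); pairs whose fragment avoids all insertions are
    concordant.
    """
    if insert_mean <= 2 * read_len:
        raise ValueError("insert_mean must exceed twice the read length")
    rng = np.random.default_rng(seed)
    template, refmap = _build_template(genome, list(insertions))
    # inserted-segment lookup: for each template base, index of insertion or -1
    seg_index = np.full(len(template), -1, dtype=np.int64)
    cursor = 0
    ordered = sorted(insertions, key=lambda i: i.site)
    for j, ins in enumerate(ordered):
        ins_start = ins.insertion_point + sum(
            len(p.inserted_sequence) for p in ordered[:j]
        )
        seg_index[ins_start : ins_start + len(ins.inserted_sequence)] = j

    pairs = []
    for idx in range(n_pairs):
        frag_len = max(2 * read_len + 1, int(rng.normal(insert_mean, insert_sd)))
        if frag_len >= len(template):
            frag_len = len(template) - 1
        start = int(rng.integers(0, len(template) - frag_len + 1))
        frag = template[start : start + frag_len]
        m1 = (start, start + read_len)
        m2 = (start + frag_len - read_len, start + frag_len)
        classes = []
        genome_positions = []
        families = []
        for lo, hi in (m1, m2):
            segs = seg_index[lo:hi]
            if (segs >= 0).all() and len(set(segs.tolist())) == 1:
                classes.append("te")
                genome_positions.append(None)
                families.append(ordered[int(segs[0])].family)
            elif (segs < 0).all():
                classes.append("genome")
                genome_positions.append((contig, int(refmap[lo]), "+"))
                families.append(None)
            else:
                classes.append("junction")
                genome_positions.append(None)
                families.append(None)
        frag_segs = seg_index[start : start + frag_len]
        concordant = bool((frag_segs < 0).all())
        seq1 = _mutate(frag[:read_len], profile, rng)
        seq2 = revcomp(_mutate(frag[-read_len:], profile, rng))
        pairs.append(
            SimPair(
                name=f"pair{idx:06d}",
                seq1=seq1,
                seq2=seq2,
                class1=classes[0],
                class2=classes[1],
                genome_pos1=genome_positions[0],
                genome_pos2=genome_positions[1],
                family1=families[0],
                family2=families[1],
                concordant=concordant,
            )
        )
    return pairs


def _mutate(seq: str, profile: ErrorProfile, rng: np.random.Generator) -> str:
    if profile.total == 0:
        return seq
    chars = []
    for ch in seq:
        r = rng.random()
        if r < profile.deletion_rate:
            continue
        if r < profile.deletion_rate + profile.substitution_rate:
            ch = str(rng.choice(BASES))
        chars.append(ch)
        if rng.random() < profile.insertion_rate:
            chars.append(str(rng.choice(BASES)))
    return "".join(chars)


def to_mate_pairs(pairs: Iterable[SimPair]):
    """Truth-based mapper surrogate: SimPairs -> shortread MatePair records."""
    from .shortread_tei import MateMapping, MatePair

    out = []
    for p in pairs:
        mates = []
        for cls, gpos, fam in (
            (p.class1, p.genome_pos1, p.family1),
            (p.class2, p.genome_pos2, p.family2),
        ):
            mates.append(
                MateMapping(
                    genome=gpos if cls == "genome" else None,
                    te_family=fam if cls == "te" else None,
                )
            )
        out.append(
            MatePair(
                read_id=p.name,
                mate1=mates[0],
                mate2=mates[1],
                concordant=p.concordant,
            )
        )
    return out


def assembly_alignment_sam(
    reference: str,
    truth: Sequence[SimInsertion],
    path: str | Path,
    *,
    contig: str = "chr_sim",
    assembly_name: str = "assembly",
) -> None:
    """Write the assembly-vs-reference alignment implied by the truth.

    Produces a single SAM record whose CIGAR carries one insertion op of
    length TE + TSD at each implanted breakpoint — the form an external
    whole-genome aligner reports for assembly-only insertions.
    """
    ordered = sorted(truth, key=lambda i: i.site)
    ops: list[tuple[int, int]] = []
    parts = []
    cursor = 0
    for ins in ordered:
        bp = ins.insertion_point
        if bp > cursor:
            ops.append((0, bp - cursor))
            parts.append(reference[cursor:bp])
        # assembly = ref[:bp] + TE + TSD + ref[bp:], so the whole extra
        # segment is one insertion op at the breakpoint
        ops.append((1, len(ins.inserted_sequence)))
        parts.append(ins.inserted_sequence)
        cursor = bp
    if cursor < len(reference):
        ops.append((0, len(reference) - cursor))
        parts.append(reference[cursor:])
    # merge adjacent M ops
    merged: list[tuple[int, int]] = []
    for op, ln in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": contig, "LN": len(reference)}],
        }
    )
    seg = pysam.AlignedSegment(header)
    seg.query_name = assembly_name
    seg.query_sequence = "".join(parts)
    seg.flag = 0
    seg.reference_id = 0
    seg.reference_start = 0
    seg.mapping_quality = 60
    seg.cigartuples = merged
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        fh.write(seg)


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    """Write sequences to FASTA (70-column wrap)."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_fastq(reads: Iterable[SimRead], path: str | Path, quality: int = 20) -> None:
    """Write simulated reads to FASTQ with a constant quality."""
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.name}\n{read.sequence}\n+\n{qchar * len(read.sequence)}\n")


def write_sam(
    reads: Iterable[SimRead],
    path: str | Path,
    *,
    contig: str = "chr_sim",
    contig_length: int,
) -> None:
    """Write simulated reads with their true alignments to SAM."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": contig, "LN": contig_length}],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for read in reads:
            fh.write(read.to_aligned_segment(header))
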