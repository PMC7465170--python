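"""TE insertion detection from Illumina discordant read pairs.

A discordant pair has one mate on the reference genome, the other on a TE
consensus, and no concordant genomic placement; the genome-side positions
are clustered per TE family so that consecutive reads are never more than
100 bp apart, each cluster is reported at the mean of its member positions,
and only clusters supported by at least 50 reads are retained by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pysam

logger = logging.getLogger(__name__)

MAX_GAP = 100
MIN_READS = 50


@dataclass(frozen=True)
class MateMapping:
    """Where one mate of a pair mapped (either compartment may be empty)."""

    genome: tuple[str, int, str] | None = None  # (contig, 0-based pos, strand)
    te_family: str | None = None


@dataclass(frozen=True)
class MatePair:
    """Joint mapping state of a read pair across genome and TE references."""

    read_id: str
    mate1: MateMapping
    mate2: MateMapping
    concordant: bool = False


@dataclass(frozen=True)
class DiscordantPair:
    """A pair anchoring a TE family at a genomic position."""

    read_id: str
    contig: str
    genome_pos: int
    te_family: str
    genome_mate_strand: str


@dataclass(frozen=True)
class TEICluster:
    """A cluster of discordant-pair anchors supporting one insertion."""

    contig: str
    position: int
    te_family: str
    member_positions: tuple[int, ...]

    @property
    def n_reads(self) -> int:
        return len(self.member_positions)


def find_discordant(pairs: Iterable[MatePair]) -> list[DiscordantPair]:
    """Select pairs with one genome-mapped and one TE-mapped mate.

    Pairs with a concordant genomic placement, both mates on the genome, or
    both mates on TE sequences are ignored.
    """
    out = []
    for pair in pairs:
        if pair.concordant:
            continue
        for genome_mate, te_mate in (
            (pair.mate1, pair.mate2),
            (pair.mate2, pair.mate1),
        ):
            if genome_mate.genome is None or te_mate.te_family is None:
                continue
            # the genome mate must not itself be a TE hit, and vice versa
            if genome_mate.te_family is not None or te_mate.genome is not None:
                continue
            contig, pos, strand = genome_mate.genome
            out.append(
                DiscordantPair(
                    read_id=pair.read_id,
                    contig=contig,
                    genome_pos=pos,
                    te_family=te_mate.te_family,
                    genome_mate_strand=strand,
                )
            )
            break
    return out


def pairs_from_bams(
    genome_sam: str | Path, te_sam: str | Path
) -> list[MatePair]:
    """Join per-mate mappings from a genome SAM/BAM and a TE SAM/BAM.

    Both files are read fully; mates are joined on (name, first/second of
    pair). Records whose mate never appears are skipped and counted in the
    log. Concordance is taken from the genome file's proper-pair flag.
    """
    genome_hits: dict[tuple[str, bool], tuple[str, int, str]] = {}
    concordant: set[str] = set()
    names: set[tuple[str, bool]] = set()
    with pysam.AlignmentFile(str(genome_sam), check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary:
                continue
            key = (rec.query_name, rec.is_read1)
            names.add(key)
            if not rec.is_unmapped:
                strand = "-" if rec.is_reverse else "+"
                genome_hits[key] = (rec.reference_name, rec.reference_start, strand)
                if rec.is_proper_pair:
                    concordant.add(rec.query_name)
    te_hits: dict[tuple[str, bool], str] = {}
    with pysam.AlignmentFile(str(te_sam), check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
                continue
            key = (rec.query_name, rec.is_read1)
            names.add(key)
            te_hits[key] = rec.reference_name

    by_name: dict[str, set[bool]] = {}
    for name, is_read1 in names:
        by_name.setdefault(name, set()).add(is_read1)
    orphans = sum(1 for mates in by_name.values() if len(mates) < 2)
    if orphans:
        logger.warning("skipped %d orphan read(s) without a mate", orphans)

    pairs = []
    for name, mates in sorted(by_name.items()):
        if len(mates) < 2:
            continue
        mate_maps = {}
        for is_read1 in (True, False):
            key = (name, is_read1)
            mate_maps[is_read1] = MateMapping(
                genome=genome_hits.get(key), te_family=te_hits.get(key)
            )
        pairs.append(
            MatePair(
                read_id=name,
                mate1=mate_maps[True],
                mate2=mate_maps[False],
                concordant=name in concordant,
            )
        )
    return pairs


def cluster_pairs(
    pairs: Iterable[DiscordantPair], *, max_gap: int = MAX_GAP
) -> list[TEICluster]:
    """Single-linkage clustering of anchors per (contig, family).

    Consecutive sorted member positions in a cluster differ by at most
    ``max_gap`` (inclusive); the cluster position is the rounded mean.
    """
    groups: dict[tuple[str, str], list[int]] = {}
    for p in pairs:
        groups.setdefault((p.contig, p.te_family), []).append(p.genome_pos)
    clusters = []
    for (contig, family), positions in sorted(groups.items()):
        positions.sort()
        current = [positions[0]]
        for pos in positions[1:]:
            if pos - current[-1] <= max_gap:
                current.append(pos)
            else:
                clusters.append(_make_cluster(contig, family, current))
                current = [pos]
        clusters.append(_make_cluster(contig, family, current))
    clusters.sort(key=lambda c: (c.contig, c.position, c.te_family))
    return clusters


def _make_cluster(contig: str, family: str, positions: list[int]) -> TEICluster:
    return TEICluster(
        contig=contig,
        position=int(round(sum(positions) / len(positions))),
        te_family=family,
        member_positions=tuple(positions),
    )


def filter_clusters(
    clusters: Iterable[TEICluster], *, min_reads: int = MIN_READS
) -> list[TEICluster]:
    """Keep clusters supported by at least ``min_reads`` pairs."""
    return [c for c in clusters if c.n_reads >= min_reads]
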