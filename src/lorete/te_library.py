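"""TE consensus library handling.

A library couples a FASTA of family consensus sequences with a tabular
annotation giving each family's group (DNA transposon, LINE or LTR
retrotransposon) and, when known, the expected target-site-duplication
size created at integration (2–18 nt across described LTR elements).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_GROUPS = frozenset({"DNA", "LINE", "LTR"})
TSD_RANGE = (2, 18)

#: Default expected TSD sizes for the six intensively studied LTR families.
#: ZAM makes a 4-nt duplication; the others default to 5 nt and can be
#: overridden via the annotation table.
DEFAULT_TSD_SIZES: dict[str, int] = {
    "ZAM": 4,
    "gtwin": 5,
    "roo": 5,
    "copia": 5,
    "blood": 5,
    "mdg3": 5,
}

_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class TEConsensus:
    """A named TE family consensus sequence."""

    name: str
    group: str
    sequence: str
    expected_tsd_size: int | str = "unknown"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("family name must be non-empty")
        if self.group not in VALID_GROUPS:
            raise ValueError(f"invalid group {self.group!r} for {self.name}")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1:
            raise ValueError(f"empty consensus sequence for {self.name}")
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(f"non-ACGTN characters in {self.name}: {sorted(bad)}")
        k = self.expected_tsd_size
        if k != "unknown":
            if not isinstance(k, int) or not TSD_RANGE[0] <= k <= TSD_RANGE[1]:
                raise ValueError(
                    f"expected_tsd_size for {self.name} must be an int in "
                    f"[{TSD_RANGE[0]}, {TSD_RANGE[1]}] or 'unknown', got {k!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TELibrary:
    """An ordered collection of TE family consensi with unique names."""

    entries: list[TEConsensus] = field(default_factory=list)
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate family name(s): {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, name: str) -> TEConsensus:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(e.name == name for e in self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]


def load_te_library(
    consensus_file: str | Path,
    annotation_file: str | Path,
    *,
    default_tsd_sizes: dict[str, int] | None = None,
) -> TELibrary:
    """Load a TE library from a consensus FASTA and a TSV annotation.

    The annotation has two or three columns: family name, group
    (DNA/LINE/LTR), and an optional expected TSD size in nt. Every FASTA
    record must be annotated; families whose TSD size is absent fall back
    to ``default_tsd_sizes`` (the shipped six-family defaults) or
    ``"unknown"``.
    """
    defaults = DEFAULT_TSD_SIZES if default_tsd_sizes is None else default_tsd_sizes
    annot: dict[str, tuple[str, int | str]] = {}
    with open(annotation_file) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            name, group = row[0], row[1]
            if name in annot:
                raise ValueError(f"duplicate annotation row for {name!r}")
            tsd: int | str = "unknown"
            if len(row) > 2 and row[2].strip():
                tsd = int(row[2])
            elif name in defaults:
                tsd = defaults[name]
            annot[name] = (group, tsd)

    entries = []
    seen = set()
    for rec in SeqIO.parse(str(consensus_file), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate family name in FASTA: {rec.id!r}")
        seen.add(rec.id)
        if rec.id not in annot:
            raise ValueError(f"FASTA record {rec.id!r} missing from annotation")
        group, tsd = annot[rec.id]
        entries.append(
            TEConsensus(
                name=rec.id, group=group, sequence=str(rec.seq), expected_tsd_size=tsd
            )
        )
    extra = set(annot) - seen
    if extra:
        raise ValueError(f"annotation rows without FASTA sequence: {sorted(extra)}")
    return TELibrary(
        entries=entries, provenance=(str(consensus_file), str(annotation_file))
    )


def write_te_library(
    lib: TELibrary, consensus_file: str | Path, annotation_file: str | Path
) -> None:
    """Write a library back to FASTA + TSV (round-trips with the loader)."""
    records = [
        SeqRecord(Seq(e.sequence), id=e.name, description="") for e in lib.entries
    ]
    SeqIO.write(records, str(consensus_file), "fasta")
    with open(annotation_file, "w") as fh:
        for e in lib.entries:
            tsd = "" if e.expected_tsd_size == "unknown" else str(e.expected_tsd_size)
            fh.write(f"{e.name}\t{e.group}\t{tsd}\n")


def ltr_subset(lib: TELibrary) -> TELibrary:
    """The LTR-retrotransposon subset of a library, order preserved."""
    return TELibrary(
        entries=[e for e in lib.entries if e.group == "LTR"],
        provenance=lib.provenance,
    )
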