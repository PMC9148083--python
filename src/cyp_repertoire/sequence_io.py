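"""Readers and writers for proteomes, reference panels, registries and
cluster tables.

All genomic coordinates are 1-based inclusive (GFF convention); every file
written by this module carries a version banner comment and, for coordinate
tables, a comment stating the convention.  Species/class metadata lives in a
separate registry TSV rather than FASTA headers so proteome files stay
standard multi-FASTA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import VERSION_BANNER

PROTEOBACTERIAL_CLASSES = ("Alpha", "Beta", "Gamma", "Delta", "Epsilon")

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

_FAMILY_RE = re.compile(r"^CYP\d+$|^NEWFAM\d+$")
_SUBFAMILY_RE = re.compile(r"^(CYP\d+|NEWFAM\d+)[A-Z]+$")


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence tied to a species."""

    protein_id: str
    species_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.protein_id!r}")
        if re.search(r"\s", self.protein_id):
            raise ValueError(f"protein_id contains whitespace: {self.protein_id!r}")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"{self.protein_id!r}: non-amino-acid symbols {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RegistryEntry:
    species_id: str
    class_label: str
    genus: str

    def __post_init__(self) -> None:
        if self.class_label not in PROTEOBACTERIAL_CLASSES:
            raise ValueError(
                f"unknown class {self.class_label!r}; "
                f"expected one of {PROTEOBACTERIAL_CLASSES}"
            )


@dataclass
class SpeciesRegistry:
    """Maps species ids to their proteobacterial class and genus."""

    entries: list[RegistryEntry]

    def __post_init__(self) -> None:
        ids = [e.species_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate species ids in registry: {dup}")

    def class_of(self, species_id: str) -> str:
        for e in self.entries:
            if e.species_id == species_id:
                return e.class_label
        raise KeyError(species_id)

    def species_by_class(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {c: [] for c in PROTEOBACTERIAL_CLASSES}
        for e in self.entries:
            out[e.class_label].append(e.species_id)
        return out


@dataclass(frozen=True)
class PanelEntry:
    ref_id: str
    family_name: str
    subfamily_name: str
    sequence: str


@dataclass
class ReferencePanel:
    """Named CYP family/subfamily exemplar sequences."""

    entries: list[PanelEntry]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.ref_id in seen:
                raise ValueError(f"duplicate ref_id {e.ref_id!r}")
            seen.add(e.ref_id)
            validate_cyp_names(e.family_name, e.subfamily_name)

    @property
    def families(self) -> list[str]:
        return sorted({e.family_name for e in self.entries})


def validate_cyp_names(family_name: str, subfamily_name: str) -> None:
    if not _FAMILY_RE.match(family_name):
        raise ValueError(f"malformed family name {family_name!r}")
    m = _SUBFAMILY_RE.match(subfamily_name)
    if not m:
        raise ValueError(f"malformed subfamily name {subfamily_name!r}")
    if m.group(1) != family_name:
        raise ValueError(
            f"subfamily {subfamily_name!r} does not belong to family {family_name!r}"
        )


@dataclass(frozen=True)
class GeneCoordinate:
    protein_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"{self.protein_id!r}: bad interval [{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.protein_id!r}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class BGCCluster:
    cluster_id: str
    species_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    cluster_type: str  # antiSMASH terminology, preserved verbatim

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"cluster {self.cluster_id!r}: bad interval [{self.start}, {self.end}]"
            )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, species_id: str | None = None) -> list[ProteinRecord]:
    """Read a proteome multi-FASTA into ProteinRecords.

    Header token 1 is the protein id; token 2, when present, is the species
    id (overridden by the ``species_id`` argument).  Sequences are
    uppercased and a terminal ``*`` stop symbol is stripped.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[tuple[str, str]] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = rec.description.split()
        pid = tokens[0]
        sp = species_id or (tokens[1] if len(tokens) > 1 else "unknown")
        seq = str(rec.seq).upper().rstrip("*")
        key = (sp, pid)
        if key in seen:
            raise ValueError(f"duplicate protein_id {pid!r} in species {sp!r}")
        seen.add(key)
        records.append(ProteinRecord(protein_id=pid, species_id=sp, sequence=seq))
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as multi-FASTA, wrapped at 60 columns."""
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description=r.species_id)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# TSV tables

def _read_tsv_rows(path: str | Path, required: list[str]) -> list[dict[str, str]]:
    path = Path(path)
    header: list[str] | None = None
    rows: list[dict[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in required if c not in header]
                if missing:
                    raise ValueError(f"{path}: missing columns {missing}")
                continue
            rows.append(dict(zip(header, fields)))
    if header is None:
        raise ValueError(f"{path}: empty file, expected a header row")
    return rows


def read_registry(path: str | Path) -> SpeciesRegistry:
    rows = _read_tsv_rows(path, ["species_id", "class_label", "genus"])
    return SpeciesRegistry(
        entries=[
            RegistryEntry(r["species_id"], r["class_label"], r["genus"]) for r in rows
        ]
    )


def write_registry(registry: SpeciesRegistry, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(VERSION_BANNER + "\n")
        fh.write("species_id\tclass_label\tgenus\n")
        for e in registry.entries:
            fh.write(f"{e.species_id}\t{e.class_label}\t{e.genus}\n")


def read_reference_panel(fasta_path: str | Path, tsv_path: str | Path) -> ReferencePanel:
    """Join panel sequences (FASTA) with family metadata (TSV)."""
    seqs = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper().rstrip("*")
    rows = _read_tsv_rows(tsv_path, ["ref_id", "family", "subfamily"])
    entries = []
    for r in rows:
        if r["ref_id"] not in seqs:
            raise ValueError(f"ref {r['ref_id']!r} in TSV but not in FASTA")
        entries.append(
            PanelEntry(
                ref_id=r["ref_id"],
                family_name=r["family"],
                subfamily_name=r["subfamily"],
                sequence=seqs[r["ref_id"]],
            )
        )
    return ReferencePanel(entries=entries)


def write_reference_panel(
    panel: ReferencePanel, fasta_path: str | Path, tsv_path: str | Path
) -> None:
    write_fasta(
        [
            ProteinRecord(e.ref_id, "panel", e.sequence)
            for e in panel.entries
        ],
        fasta_path,
    )
    with open(tsv_path, "w") as fh:
        fh.write(VERSION_BANNER + "\n")
        fh.write("ref_id\tfamily\tsubfamily\n")
        for e in panel.entries:
            fh.write(f"{e.ref_id}\t{e.family_name}\t{e.subfamily_name}\n")


def read_bgc_table(path: str | Path) -> list[BGCCluster]:
    rows = _read_tsv_rows(
        path, ["cluster_id", "species_id", "contig", "start", "end", "cluster_type"]
    )
    clusters = []
    for i, r in enumerate(rows, start=1):
        try:
            clusters.append(
                BGCCluster(
                    cluster_id=r["cluster_id"],
                    species_id=r["species_id"],
                    contig=r["contig"],
                    start=int(r["start"]),
                    end=int(r["end"]),
                    cluster_type=r["cluster_type"],
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}, row {i}: {exc}") from exc
    return clusters


def write_bgc_table(clusters: Iterable[BGCCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(VERSION_BANNER + "\n")
        fh.write("# coordinates 1-based inclusive\n")
        fh.write("cluster_id\tspecies_id\tcontig\tstart\tend\tcluster_type\n")
        for c in clusters:
            fh.write(
                f"{c.cluster_id}\t{c.species_id}\t{c.contig}\t"
                f"{c.start}\t{c.end}\t{c.cluster_type}\n"
            )


def read_gene_coords(path: str | Path) -> list[GeneCoordinate]:
    rows = _read_tsv_rows(path, ["protein_id", "contig", "start", "end", "strand"])
    coords = []
    for i, r in enumerate(rows, start=1):
        try:
            coords.append(
                GeneCoordinate(
                    protein_id=r["protein_id"],
                    contig=r["contig"],
                    start=int(r["start"]),
                    end=int(r["end"]),
                    strand=r["strand"],
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}, row {i}: {exc}") from exc
    return coords


def write_gene_coords(coords: Iterable[GeneCoordinate], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(VERSION_BANNER + "\n")
        fh.write("# coordinates 1-based inclusive\n")
        fh.write("protein_id\tcontig\tstart\tend\tstrand\n")
        for c in coords:
            fh.write(f"{c.protein_id}\t{c.contig}\t{c.start}\t{c.end}\t{c.strand}\n")
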