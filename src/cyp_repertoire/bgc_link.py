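"""Linking P450 genes to secondary-metabolite biosynthetic gene clusters.

A P450 is "part of" a cluster when its gene interval overlaps the cluster
interval on the same contig of the same species.  The default rule is
any-overlap (≥1 bp); a stricter "contained" rule (gene fully inside the
cluster) is available for sensitivity analysis.  Amino-acid products are
mapped to nucleotide intervals through the gene-coordinate table; a P450
overlapping two clusters links to both but counts once in totals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from . import VERSION_BANNER
from .family_assign import FamilyAssignment
from .sequence_io import BGCCluster, GeneCoordinate, SpeciesRegistry

OVERLAP_ANY = "any"
OVERLAP_CONTAINED = "contained"


@dataclass(frozen=True)
class BGCLink:
    query_id: str
    cluster_id: str
    cluster_type: str


@dataclass
class BGCLinkTable:
    """Per-class family → member-count table of cluster-borne P450s."""

    class_label: str
    rows: list[tuple[str, int]]  # (family_name, count), counts ≥ 1

    @property
    def total(self) -> int:
        return sum(c for _, c in self.rows)

    @property
    def n_families(self) -> int:
        return len(self.rows)


def _overlaps(gene: GeneCoordinate, cluster: BGCCluster, rule: str) -> bool:
    if rule == OVERLAP_ANY:
        return gene.start <= cluster.end and gene.end >= cluster.start
    if rule == OVERLAP_CONTAINED:
        return gene.start >= cluster.start and gene.end <= cluster.end
    raise ValueError(f"unknown overlap rule {rule!r}")


def link_p450s(
    assignments: list[FamilyAssignment],
    gene_coords: list[GeneCoordinate],
    clusters: list[BGCCluster],
    overlap_rule: str = OVERLAP_ANY,
) -> list[BGCLink]:
    """Link assigned P450s to the clusters their genes overlap.

    P450s with no coordinate row are excluded with a warning (not an
    error).  Output order follows sorted (query_id, cluster_id), making
    linkage invariant to input row order.
    """
    coords = {c.protein_id: c for c in gene_coords}
    species_of = {a.query_id: a.species_id for a in assignments}
    by_species: dict[str, list[BGCCluster]] = {}
    for cl in clusters:
        by_species.setdefault(cl.species_id, []).append(cl)
    links = []
    for a in assignments:
        gene = coords.get(a.query_id)
        if gene is None:
            warnings.warn(
                f"P450 {a.query_id!r} has no gene coordinates; excluded from "
                "cluster linkage",
                stacklevel=2,
            )
            continue
        for cl in by_species.get(species_of[a.query_id], []):
            if cl.contig == gene.contig and _overlaps(gene, cl, overlap_rule):
                links.append(BGCLink(a.query_id, cl.cluster_id, cl.cluster_type))
    return sorted(links, key=lambda l: (l.query_id, l.cluster_id))


def tabulate_bgc_families(
    links: list[BGCLink],
    assignments: list[FamilyAssignment],
    registry: SpeciesRegistry,
) -> dict[str, BGCLinkTable]:
    """Per-class family → member-count tables of cluster-borne P450s.

    Each distinct linked P450 counts once, under its assigned family, in
    the class of its species.  Rows sort by descending count, then family
    name.
    """
    assign_by_id = {a.query_id: a for a in assignments}
    linked_ids = sorted({l.query_id for l in links})
    per_class: dict[str, dict[str, int]] = {}
    for qid in linked_ids:
        a = assign_by_id[qid]
        cls = registry.class_of(a.species_id)
        fam_counts = per_class.setdefault(cls, {})
        fam_counts[a.family_name] = fam_counts.get(a.family_name, 0) + 1
    tables = {}
    for cls, fam_counts in per_class.items():
        rows = sorted(fam_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        tables[cls] = BGCLinkTable(class_label=cls, rows=rows)
    return tables


def write_links(links: list[BGCLink], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(VERSION_BANNER + "\n")
        fh.write("query_id\tcluster_id\tcluster_type\n")
        for l in links:
            fh.write(f"{l.query_id}\t{l.cluster_id}\t{l.cluster_type}\n")


def read_links(path: str | Path) -> list[BGCLink]:
    from .sequence_io import _read_tsv_rows

    rows = _read_tsv_rows(path, ["query_id", "cluster_id", "cluster_type"])
    return [BGCLink(r["query_id"], r["cluster_id"], r["cluster_type"]) for r in rows]


def write_bgc_family_tables(
    tables: dict[str, BGCLinkTable], path: str | Path
) -> None:
    """One TSV with class, family, count columns, classes in fixed order."""
    from .sequence_io import PROTEOBACTERIAL_CLASSES

    with open(path, "w") as fh:
        fh.write(VERSION_BANNER + "\n")
        fh.write("class_label\tfamily\tcount\n")
        for cls in PROTEOBACTERIAL_CLASSES:
            if cls not in tables:
                continue
            for fam, count in tables[cls].rows:
                fh.write(f"{cls}\t{fam}\t{count}\n")
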