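"""Cross-class P450 family conservation structures.

Presence/absence of each family per proteobacterial class, coded 3
(present) / −3 (absent) for heat-map import, with rows ordered by
agglomerative hierarchical clustering (Euclidean distance, average
linkage); and the Venn partition assigning every family to the exact
subset of classes it occurs in.  The epsilon class is excluded from the
4-way Venn by default because its two families make it uninformative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage

from . import VERSION_BANNER
from .family_assign import FamilyAssignment
from .sequence_io import PROTEOBACTERIAL_CLASSES, SpeciesRegistry

PRESENT = 3
ABSENT = -3


@dataclass
class PresenceMatrix:
    families: list[str]  # clustered row order
    classes: list[str]
    values: np.ndarray  # entries in {-3, 3}, shape (families, classes)


@dataclass
class VennPartition:
    """count of families present in exactly each non-empty class subset"""

    counts: dict[frozenset, int]

    def unique(self, class_label: str) -> int:
        return self.counts.get(frozenset({class_label}), 0)

    @property
    def core(self) -> int:
        universe = frozenset().union(*self.counts) if self.counts else frozenset()
        return self.counts.get(universe, 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def family_sets_by_class(
    assignments: list[FamilyAssignment], registry: SpeciesRegistry
) -> dict[str, set[str]]:
    """Which families have ≥1 member in each class."""
    sets: dict[str, set[str]] = {}
    for a in assignments:
        cls = registry.class_of(a.species_id)
        sets.setdefault(cls, set()).add(a.family_name)
    return sets


def order_rows(matrix: np.ndarray, method: str = "average") -> list[int]:
    """Dendrogram leaf order from hierarchical clustering of the rows.

    Euclidean distance; deterministic tie-breaking (lower original index
    merges first).  A single row returns the identity permutation.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        return list(range(matrix.shape[0]))
    Z = linkage(matrix, method=method, metric="euclidean")
    return [int(i) for i in leaves_list(Z)]


def build_presence(
    family_sets: dict[str, set[str]],
    classes: list[str] | None = None,
    cluster_rows: bool = True,
    method: str = "average",
) -> PresenceMatrix:
    """3/−3 presence matrix over all families seen in the given classes.

    Rows are families (clustered order when requested), columns the
    classes in their given, fixed order (columns are never clustered).
    """
    if classes is None:
        classes = [c for c in PROTEOBACTERIAL_CLASSES if c in family_sets]
    if not classes:
        raise ValueError("need at least one class")
    families = sorted(set().union(*(family_sets.get(c, set()) for c in classes)))
    values = np.full((len(families), len(classes)), ABSENT, dtype=int)
    for j, cls in enumerate(classes):
        members = family_sets.get(cls, set())
        for i, fam in enumerate(families):
            if fam in members:
                values[i, j] = PRESENT
    if cluster_rows and len(families) >= 2:
        perm = order_rows(values, method=method)
        families = [families[i] for i in perm]
        values = values[perm]
    return PresenceMatrix(families=families, classes=list(classes), values=values)


def venn_counts(family_sets: dict[str, set[str]]) -> VennPartition:
    """Partition families by the exact subset of classes containing them."""
    if len(family_sets) < 2:
        raise ValueError("need at least two classes for a Venn partition")
    counts: dict[frozenset, int] = {}
    all_families = set().union(*family_sets.values())
    for fam in all_families:
        subset = frozenset(c for c, fams in family_sets.items() if fam in fams)
        counts[subset] = counts.get(subset, 0) + 1
    return VennPartition(counts=counts)


def write_presence_tsv(matrix: PresenceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(VERSION_BANNER + "\n")
        fh.write("family\t" + "\t".join(matrix.classes) + "\n")
        for fam, row in zip(matrix.families, matrix.values):
            fh.write(fam + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def write_venn_json(partition: VennPartition, path: str | Path) -> None:
    serializable = {
        "+".join(sorted(subset)): count
        for subset, count in sorted(
            partition.counts.items(), key=lambda kv: "+".join(sorted(kv[0]))
        )
    }
    with open(path, "w") as fh:
        json.dump(serializable, fh, indent=2)
        fh.write("\n")
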