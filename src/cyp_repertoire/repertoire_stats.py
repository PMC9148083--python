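"""Per-class P450 repertoire statistics.

Three published summary statistics, computed per proteobacterial class:

  average P450s      = n_P450s / n_species_with_P450s, to nearest integer
  diversity %        = 100 × n_families / (n_P450s × n_species_with_P450s),
                       to 2 decimals — a per-class richness index
  % P450s in BGCs    = 100 × n_BGC_P450s / n_P450s, to nearest integer

plus the percentage of species carrying any P450.  All rounding is
half-away-from-zero, exact decimal arithmetic (no float division), which
reproduces every published rounded value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

from . import VERSION_BANNER
from .bgc_link import BGCLink
from .family_assign import FamilyAssignment
from .p450_detect import P450Candidate
from .sequence_io import PROTEOBACTERIAL_CLASSES, SpeciesRegistry


def _round_half_away(value: Decimal, places: int) -> Decimal:
    q = Decimal(1).scaleb(-places)
    return value.quantize(q, rounding=ROUND_HALF_UP)


def average_p450(n_p450: int, n_species_with_p450: int) -> int:
    """Average P450s per P450-carrying species, nearest integer."""
    if n_species_with_p450 < 1:
        raise ValueError("no species with P450s: average undefined")
    return int(_round_half_away(Decimal(n_p450) / Decimal(n_species_with_p450), 0))


def diversity_pct(n_families: int, n_p450: int, n_species_with_p450: int) -> float:
    """P450 diversity percentage, rounded to two decimals.

    100 × families / (P450s × species-with-P450s): high when a small
    P450 complement spread over few species still spans many families.
    """
    if n_p450 < 1 or n_species_with_p450 < 1:
        raise ValueError("diversity undefined without P450s and carrier species")
    value = (Decimal(100) * Decimal(n_families)) / (
        Decimal(n_p450) * Decimal(n_species_with_p450)
    )
    return float(_round_half_away(value, 2))


def pct_bgc(n_bgc_p450: int, n_p450: int) -> int:
    """Percentage of P450s inside biosynthetic gene clusters, integer."""
    if n_p450 < 1:
        raise ValueError("no P450s: percentage undefined")
    return int(_round_half_away(Decimal(100) * Decimal(n_bgc_p450) / Decimal(n_p450), 0))


def pct_species(n_with: int, n_analyzed: int) -> int:
    """Percentage of analyzed species carrying at least one P450."""
    if n_analyzed < 1:
        raise ValueError("no species analyzed")
    return int(_round_half_away(Decimal(100) * Decimal(n_with) / Decimal(n_analyzed), 0))


def dominant_family(census: dict[str, int]) -> list[str]:
    """All families attaining the maximum member count (ties joint)."""
    if not census:
        raise ValueError("empty family census")
    top = max(census.values())
    return sorted(f for f, c in census.items() if c == top)


@dataclass
class ClassSummary:
    class_label: str
    n_species_analyzed: int
    n_species_with_p450: int
    pct_species_with_p450: int
    n_p450: int
    n_families: int
    n_subfamilies: int
    dominant_families: list[str]
    avg_p450: int
    diversity_pct: float
    n_bgc_p450: int
    n_bgc_families: int
    pct_bgc_p450: int
    undefined: bool = False  # class had no P450s; derived fields forced to 0


def summarize_class(
    class_label: str,
    registry: SpeciesRegistry,
    candidates: list[P450Candidate],
    assignments: list[FamilyAssignment],
    links: list[BGCLink],
) -> ClassSummary:
    """Assemble one class's summary column from the raw pipeline outputs."""
    class_species = set(registry.species_by_class()[class_label])
    class_assignments = [a for a in assignments if a.species_id in class_species]
    n_p450 = len(class_assignments)
    species_with = {a.species_id for a in class_assignments}
    families = {a.family_name for a in class_assignments}
    subfamilies = {a.subfamily_name for a in class_assignments}
    census: dict[str, int] = {}
    for a in class_assignments:
        census[a.family_name] = census.get(a.family_name, 0) + 1
    class_ids = {a.query_id for a in class_assignments}
    linked_ids = {l.query_id for l in links if l.query_id in class_ids}
    bgc_families = {
        a.family_name for a in class_assignments if a.query_id in linked_ids
    }
    n_analyzed = len(class_species)
    if n_p450 == 0:
        return ClassSummary(
            class_label=class_label,
            n_species_analyzed=n_analyzed,
            n_species_with_p450=0,
            pct_species_with_p450=0 if n_analyzed == 0 else pct_species(0, n_analyzed),
            n_p450=0, n_families=0, n_subfamilies=0,
            dominant_families=[], avg_p450=0, diversity_pct=0.0,
            n_bgc_p450=0, n_bgc_families=0, pct_bgc_p450=0,
            undefined=True,
        )
    return ClassSummary(
        class_label=class_label,
        n_species_analyzed=n_analyzed,
        n_species_with_p450=len(species_with),
        pct_species_with_p450=pct_species(len(species_with), n_analyzed),
        n_p450=n_p450,
        n_families=len(families),
        n_subfamilies=len(subfamilies),
        dominant_families=dominant_family(census),
        avg_p450=average_p450(n_p450, len(species_with)),
        diversity_pct=diversity_pct(len(families), n_p450, len(species_with)),
        n_bgc_p450=len(linked_ids),
        n_bgc_families=len(bgc_families),
        pct_bgc_p450=pct_bgc(len(linked_ids), n_p450),
    )


def summarize_all(
    registry: SpeciesRegistry,
    candidates: list[P450Candidate],
    assignments: list[FamilyAssignment],
    links: list[BGCLink],
) -> list[ClassSummary]:
    present = {
        cls for cls, sp in registry.species_by_class().items() if sp
    }
    return [
        summarize_class(cls, registry, candidates, assignments, links)
        for cls in PROTEOBACTERIAL_CLASSES
        if cls in present
    ]


_METRIC_ROWS = [
    ("Species analyzed", "n_species_analyzed"),
    ("Species with P450s", "n_species_with_p450"),
    ("Percentage of species with P450s", "pct_species_with_p450"),
    ("No. of P450s", "n_p450"),
    ("No. of families", "n_families"),
    ("No. of subfamilies", "n_subfamilies"),
    ("Dominant P450 family", "dominant_families"),
    ("Average no. of P450s", "avg_p450"),
    ("P450 diversity percentage", "diversity_pct"),
    ("No. of P450s part of BGCs", "n_bgc_p450"),
    ("No. of P450 families part of BGCs", "n_bgc_families"),
    ("Percentage of P450s part of BGCs", "pct_bgc_p450"),
]


def write_summary_table(summaries: list[ClassSummary], path: str | Path) -> None:
    """Classes as columns, metrics as rows (the published table shape)."""
    with open(path, "w") as fh:
        fh.write(VERSION_BANNER + "\n")
        fh.write("Category\t" + "\t".join(s.class_label for s in summaries) + "\n")
        for label, attr in _METRIC_ROWS:
            cells = []
            for s in summaries:
                v = getattr(s, attr)
                if isinstance(v, list):
                    cells.append(" & ".join(v) if v else "-")
                elif isinstance(v, float):
                    cells.append(f"{v:.2f}")
                else:
                    cells.append(str(v))
            fh.write(label + "\t" + "\t".join(cells) + "\n")


def write_summary_json(summaries: list[ClassSummary], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(s) for s in summaries], fh, indent=2)
        fh.write("\n")
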