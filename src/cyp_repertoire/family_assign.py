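"""CYP family/subfamily assignment by percent-identity thresholds.

The International P450 Nomenclature Committee convention groups sequences
with >40% identity into one family and >55% into one subfamily; sequences
below 40% to every named reference found a new family.  Identity is
computed from a global pairwise alignment (affine gaps, BLOSUM62) with the
alignment length as denominator.  Novel families are formed greedily in
query-id order and the panel is augmented with each assigned query, so a
later query joining an earlier novel family needs >40% identity to any
already-assigned member (a chain criterion, not full pairwise identity).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix
from skbio.tree import nj

from . import VERSION_BANNER
from .p450_detect import P450Candidate
from .sequence_io import ReferencePanel

FAMILY_THRESHOLD = 40.0
SUBFAMILY_THRESHOLD = 55.0


@dataclass
class AlignParams:
    """Global-alignment settings behind percent identity.

    denominator selects what identical columns are divided by:
    "alignment-columns" (default; terminal gap columns included) or
    "shorter-sequence" for sensitivity checks.
    """

    matrix: str = "BLOSUM62"
    open_gap: float = 10.0
    extend_gap: float = 0.5
    denominator: str = "alignment-columns"

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        aligner.open_gap_score = -abs(self.open_gap)
        aligner.extend_gap_score = -abs(self.extend_gap)
        return aligner


@dataclass(frozen=True)
class IdentityResult:
    query_id: str
    ref_id: str
    percent_identity: float
    aligned_length: int


@dataclass(frozen=True)
class FamilyAssignment:
    query_id: str
    species_id: str
    family_name: str
    subfamily_name: str
    best_ref_id: str | None
    best_identity: float
    is_novel_family: bool
    is_novel_subfamily: bool


def percent_identity(
    seq_a: str,
    seq_b: str,
    params: AlignParams | None = None,
    query_id: str = "a",
    ref_id: str = "b",
) -> IdentityResult:
    """Percent identity of the optimal global alignment of two proteins.

    identities / alignment columns × 100 (no both-gap columns arise in a
    pairwise alignment).  Deterministic: the first optimal traceback is
    used, and identity counts are symmetric in the arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    params = params or AlignParams()
    aligner = params.make_aligner()
    # canonical argument order keeps pid(a,b) == pid(b,a) even when
    # co-optimal tracebacks would differ
    flipped = seq_b < seq_a
    first, second = (seq_b, seq_a) if flipped else (seq_a, seq_b)
    alignment = aligner.align(first, second)[0]
    counts = alignment.counts()
    columns = alignment.length
    if params.denominator == "shorter-sequence":
        denom = min(len(seq_a), len(seq_b))
    elif params.denominator == "alignment-columns":
        denom = columns
    else:
        raise ValueError(f"unknown denominator {params.denominator!r}")
    pid = 100.0 * counts.identities / denom
    return IdentityResult(
        query_id=query_id, ref_id=ref_id, percent_identity=pid, aligned_length=columns
    )


def _int_to_letters(n: int) -> str:
    """0 -> A, 25 -> Z, 26 -> AA ... (spreadsheet-column style)."""
    letters = ""
    n += 1
    while n > 0:
        n, rem = divmod(n - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return letters


def _split_subfamily(family: str, subfamily: str) -> str:
    return subfamily[len(family):]


class _AugmentedPanel:
    """Reference panel that grows as queries are assigned."""

    def __init__(self, panel: ReferencePanel):
        if not panel.entries:
            raise ValueError("empty reference panel")
        self.refs: list[tuple[str, str, str, str]] = [
            (e.ref_id, e.family_name, e.subfamily_name, e.sequence)
            for e in panel.entries
        ]
        self.subfamilies: dict[str, set[str]] = {}
        for _, fam, sub, _ in self.refs:
            self.subfamilies.setdefault(fam, set()).add(_split_subfamily(fam, sub))
        self.n_newfam = 0

    def best_hit(self, seq: str, query_id: str, align_params: AlignParams):
        best: tuple[float, str, str, str] | None = None  # pid, ref_id, fam, sub
        for ref_id, fam, sub, ref_seq in self.refs:
            r = percent_identity(seq, ref_seq, align_params, query_id, ref_id)
            pid = r.percent_identity
            # ties at equal identity break to the lexicographically
            # smaller ref id
            if best is None or pid > best[0] or (pid == best[0] and ref_id < best[1]):
                best = (pid, ref_id, fam, sub)
        assert best is not None
        return best

    def new_family(self) -> tuple[str, str]:
        self.n_newfam += 1
        fam = f"NEWFAM{self.n_newfam}"
        sub = fam + "A"
        self.subfamilies[fam] = {"A"}
        return fam, sub

    def new_subfamily(self, family: str) -> str:
        used = self.subfamilies.setdefault(family, set())
        i = 0
        while _int_to_letters(i) in used:
            i += 1
        letters = _int_to_letters(i)
        used.add(letters)
        return family + letters

    def add(self, ref_id: str, family: str, subfamily: str, seq: str) -> None:
        self.refs.append((ref_id, family, subfamily, seq))
        self.subfamilies.setdefault(family, set()).add(
            _split_subfamily(family, subfamily)
        )


def _assign_one(
    candidate: P450Candidate,
    panel: _AugmentedPanel,
    align_params: AlignParams,
    family_threshold: float,
    subfamily_threshold: float,
) -> FamilyAssignment:
    rec = candidate.record
    pid, ref_id, fam, sub = panel.best_hit(rec.sequence, rec.protein_id, align_params)
    if pid > subfamily_threshold:
        assignment = FamilyAssignment(
            rec.protein_id, rec.species_id, fam, sub, ref_id, pid, False, False
        )
    elif pid > family_threshold:
        new_sub = panel.new_subfamily(fam)
        assignment = FamilyAssignment(
            rec.protein_id, rec.species_id, fam, new_sub, ref_id, pid, False, True
        )
    else:
        # below (or exactly at) the family threshold: found a new family
        new_fam, new_sub = panel.new_family()
        assignment = FamilyAssignment(
            rec.protein_id, rec.species_id, new_fam, new_sub, ref_id, pid, True, True
        )
    panel.add(rec.protein_id, assignment.family_name, assignment.subfamily_name,
              rec.sequence)
    return assignment


def assign(
    candidate: P450Candidate,
    panel: ReferencePanel,
    align_params: AlignParams | None = None,
    family_threshold: float = FAMILY_THRESHOLD,
    subfamily_threshold: float = SUBFAMILY_THRESHOLD,
) -> FamilyAssignment:
    """Assign one candidate against a fixed panel (no augmentation kept)."""
    aug = _AugmentedPanel(panel)
    return _assign_one(
        candidate, aug, align_params or AlignParams(),
        family_threshold, subfamily_threshold,
    )


def assign_all(
    candidates: list[P450Candidate],
    panel: ReferencePanel,
    align_params: AlignParams | None = None,
    family_threshold: float = FAMILY_THRESHOLD,
    subfamily_threshold: float = SUBFAMILY_THRESHOLD,
) -> tuple[list[FamilyAssignment], Counter, Counter]:
    """Assign every candidate, augmenting the panel incrementally.

    Queries are processed in sorted (species_id, protein_id) order so the
    result is independent of input order.  Returns the assignments (in
    processing order) plus family and subfamily censuses.
    """
    align_params = align_params or AlignParams()
    aug = _AugmentedPanel(panel)
    ordered = sorted(candidates, key=lambda c: (c.record.species_id,
                                                c.record.protein_id))
    assignments = [
        _assign_one(c, aug, align_params, family_threshold, subfamily_threshold)
        for c in ordered
    ]
    family_census = Counter(a.family_name for a in assignments)
    subfamily_census = Counter(a.subfamily_name for a in assignments)
    return assignments, family_census, subfamily_census


def build_tree(
    assignments: list[FamilyAssignment],
    sequences: dict[str, str],
    align_params: AlignParams | None = None,
) -> str:
    """Neighbor-joining tree on identity distances, as a newick string.

    Distance d = 1 − pid/100; leaves are labelled "<family>_<query_id>".
    """
    if len(assignments) < 3:
        raise ValueError("need at least 3 sequences for a tree")
    align_params = align_params or AlignParams()
    ids = [a.query_id for a in assignments]
    labels = [f"{a.family_name}_{a.query_id}" for a in assignments]
    n = len(ids)
    dist = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity(
                sequences[ids[i]], sequences[ids[j]], align_params
            ).percent_identity
            dist[i][j] = dist[j][i] = 1.0 - pid / 100.0
    tree = nj(DistanceMatrix(dist, labels))
    return str(tree).strip()


def write_assignments(
    assignments: list[FamilyAssignment], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(VERSION_BANNER + "\n")
        fh.write(
            "query_id\tspecies_id\tfamily\tsubfamily\tbest_ref\t"
            "best_identity\tnovel_family\tnovel_subfamily\n"
        )
        for a in assignments:
            fh.write(
                f"{a.query_id}\t{a.species_id}\t{a.family_name}\t"
                f"{a.subfamily_name}\t{a.best_ref_id or ''}\t"
                f"{a.best_identity:.2f}\t{int(a.is_novel_family)}\t"
                f"{int(a.is_novel_subfamily)}\n"
            )


def read_assignments(path: str | Path) -> list[FamilyAssignment]:
    from .sequence_io import _read_tsv_rows

    rows = _read_tsv_rows(
        path,
        ["query_id", "species_id", "family", "subfamily", "best_ref",
         "best_identity", "novel_family", "novel_subfamily"],
    )
    return [
        FamilyAssignment(
            query_id=r["query_id"],
            species_id=r["species_id"],
            family_name=r["family"],
            subfamily_name=r["subfamily"],
            best_ref_id=r["best_ref"] or None,
            best_identity=float(r["best_identity"]),
            is_novel_family=bool(int(r["novel_family"])),
            is_novel_subfamily=bool(int(r["novel_subfamily"])),
        )
        for r in rows
    ]
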