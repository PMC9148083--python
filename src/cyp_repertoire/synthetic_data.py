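"""Fully labelled synthetic inputs for the P450 mining pipeline.

Emulates the statistical structure the pipeline assumes about real
bacterial proteomes without requiring any downloads: P450-like proteins of
~400 aa carrying EXXR and CxG motifs at realistic positions, family
structure at controlled pairwise identities straddling the 40%/55%
nomenclature thresholds, truncated motif-free fragments, motif-free decoy
proteins, gene coordinates on synthetic contigs, and biosynthetic gene
cluster intervals wrapped around a configurable, exact fraction of P450
genes.  Every generated protein is recorded in a truth table, so detection
and assignment can be scored against planted ground truth.

The substitution model is uniform random replacement (no indels), so the
realized identity of a mutant is controlled by the number of substituted
positions; motif anchor residues (E/R of EXXR, C/G of CxG) are never
mutated.  Generation is deterministic under a fixed seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import VERSION_BANNER
from .family_assign import AlignParams, percent_identity
from .p450_detect import DetectionParams, scan_motifs
from .sequence_io import (
    BGCCluster,
    GeneCoordinate,
    PanelEntry,
    ProteinRecord,
    ReferencePanel,
    RegistryEntry,
    SpeciesRegistry,
    write_bgc_table,
    write_fasta,
    write_gene_coords,
    write_reference_panel,
    write_registry,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# antiSMASH cluster-type vocabulary used for synthetic intervals
CLUSTER_TYPES = ("t1pks", "nrps", "terpene", "bacteriocin", "lanthipeptide",
                 "siderophore")

IDENTITY_TOLERANCE = 3.0  # realized identity within ±3 points of target
MAX_SEPARABILITY_ATTEMPTS = 1000
MAX_DECOY_DRAWS = 10_000


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset.

    p450_mean_per_species maps each class to the Poisson mean of P450
    counts per species; the defaults mirror the published per-class
    averages (Delta-rich, Epsilon-poor).  identity_targets are the planted
    percent identities of family members to their family seed.
    """

    seed: int = 1234
    class_labels: tuple = ("Alpha", "Beta", "Gamma", "Delta", "Epsilon")
    species_per_class: int = 6
    p450_mean_per_species: dict = field(
        default_factory=lambda: {
            "Alpha": 4.0, "Beta": 2.0, "Gamma": 2.0, "Delta": 14.0, "Epsilon": 1.0,
        }
    )
    p450_distribution: str = "poisson"  # "poisson" | "constant"
    n_seed_families: int = 5
    identity_targets: tuple = (60.0, 80.0)
    fragment_fraction: float = 0.1
    decoy_count_per_species: int = 10
    bgc_fraction: float = 0.2
    min_full_length: int = 300
    seq_length: int = 400
    max_seed_identity: float = 30.0

    def __post_init__(self) -> None:
        for name in ("fragment_fraction", "bgc_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for t in self.identity_targets:
            if not 0.0 < t <= 100.0:
                raise ValueError(f"identity target out of (0, 100]: {t}")
        if self.p450_distribution not in ("poisson", "constant"):
            raise ValueError(
                f"unknown p450_distribution {self.p450_distribution!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "class_labels" in data:
            data["class_labels"] = tuple(data["class_labels"])
        if "identity_targets" in data:
            data["identity_targets"] = tuple(data["identity_targets"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["class_labels"] = list(self.class_labels)
        data["identity_targets"] = [float(t) for t in self.identity_targets]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass(frozen=True)
class TruthRow:
    protein_id: str
    species_id: str
    status: str  # p450 | fragment | decoy
    true_family: str  # "" for fragments/decoys
    true_subfamily: str
    identity_target: float  # 0 for fragments/decoys
    in_bgc: bool
    cluster_id: str  # "" when not in a cluster


@dataclass
class SynthDataset:
    config: SynthConfig
    registry: SpeciesRegistry
    panel: ReferencePanel
    seed_sequences: dict[str, str]  # family name -> seed sequence
    records: list[ProteinRecord]
    gene_coords: list[GeneCoordinate]
    clusters: list[BGCCluster]
    truth: list[TruthRow]

    def truth_by_id(self) -> dict[str, TruthRow]:
        return {t.protein_id: t for t in self.truth}


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _plant_motifs(seq: str, rng: np.random.Generator) -> tuple[str, int, int]:
    """Plant EXXR in [0.55L, 0.8L] and CxG in the last 60 residues.

    Returns the sequence and the 0-based anchor positions of the two
    motifs.  Positions are chosen so the heme loop falls downstream of the
    K-helix, as in real P450 topology.
    """
    chars = list(seq)
    L = len(chars)
    u = int(rng.integers(int(0.55 * L), int(0.8 * L)))
    chars[u] = "E"
    chars[u + 3] = "R"
    v = int(rng.integers(max(L - 60, u + 4), L - 2))
    chars[v] = "C"
    chars[v + 2] = "G"
    return "".join(chars), u, v


def make_panel(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[ReferencePanel, dict[str, str], dict[str, tuple[int, int]]]:
    """Generate mutually separable family seed sequences.

    Each seed is a random ~400-aa protein with planted motifs; seeds are
    rejection-sampled until all pairwise identities fall below
    ``max_seed_identity`` so the planted families are unambiguous.
    Returns (panel, seed sequences by family, motif anchors by family).
    """
    if config.n_seed_families < 1:
        raise ValueError("need at least one seed family")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    align = AlignParams()
    seeds: dict[str, str] = {}
    anchors: dict[str, tuple[int, int]] = {}
    entries = []
    for i in range(config.n_seed_families):
        fam = f"CYP{101 + i}"
        for attempt in range(MAX_SEPARABILITY_ATTEMPTS):
            length = int(rng.integers(config.seq_length - 20, config.seq_length + 21))
            seq, u, v = _plant_motifs(_random_sequence(rng, length), rng)
            if all(
                percent_identity(seq, other, align).percent_identity
                < config.max_seed_identity
                for other in seeds.values()
            ):
                break
        else:
            raise RuntimeError(
                f"could not generate a seed separable from {len(seeds)} others "
                f"in {MAX_SEPARABILITY_ATTEMPTS} attempts"
            )
        seeds[fam] = seq
        anchors[fam] = (u, v)
        entries.append(
            PanelEntry(ref_id=f"{fam}A1", family_name=fam,
                       subfamily_name=f"{fam}A", sequence=seq)
        )
    return ReferencePanel(entries=entries), seeds, anchors


def mutate_to_identity(
    seed_seq: str,
    target_pct: float,
    rng: np.random.Generator,
    protected: tuple[int, ...] = (),
    align_params: AlignParams | None = None,
) -> str:
    """Substitute residues until realized identity is within ±3 of target.

    Realized identity is measured with the pipeline's own global-alignment
    definition; the number of substituted positions is adjusted iteratively
    because gapped alignments of heavily mutated sequences recover more
    identities than the substitution count alone predicts.  Protected
    positions (motif anchors) are never touched.
    """
    if not 0.0 < target_pct <= 100.0:
        raise ValueError(f"target identity out of (0, 100]: {target_pct}")
    if target_pct == 100.0:
        return seed_seq
    align_params = align_params or AlignParams()
    L = len(seed_seq)
    mutable = np.array([i for i in range(L) if i not in set(protected)])
    k = min(len(mutable), max(1, round(L * (1.0 - target_pct / 100.0))))
    lo, hi = 0, len(mutable)
    for _ in range(40):
        positions = rng.choice(mutable, size=k, replace=False)
        chars = list(seed_seq)
        for p in positions:
            original = chars[p]
            alternatives = [a for a in AA20 if a != original]
            chars[p] = alternatives[int(rng.integers(len(alternatives)))]
        mutant = "".join(chars)
        realized = percent_identity(seed_seq, mutant, align_params).percent_identity
        if abs(realized - target_pct) <= IDENTITY_TOLERANCE:
            return mutant
        if realized > target_pct:  # too similar: mutate more
            lo = max(lo, k)
            k = min(hi, max(k + 1, (k + hi) // 2))
        else:
            hi = min(hi, k)
            k = max(lo, min(k - 1, (lo + k) // 2))
        if lo >= hi and abs(realized - target_pct) > IDENTITY_TOLERANCE:
            break
    raise RuntimeError(
        f"cannot reach identity {target_pct}±{IDENTITY_TOLERANCE} while "
        f"preserving {len(protected)} motif positions"
    )


_EXXR_RE = re.compile(r"(?=(E..R))")
_CXG_RE = re.compile(r"(?=(C.G))")


def _scrub_motifs(seq: str, rng: np.random.Generator) -> str:
    """Destroy every EXXR/CxG instance anywhere in the sequence."""
    chars = list(seq)
    for _ in range(100):
        s = "".join(chars)
        hits = [m.start() for m in _EXXR_RE.finditer(s)]
        hits += [m.start() for m in _CXG_RE.finditer(s)]
        if not hits:
            return s
        for h in hits:
            repl = [a for a in AA20 if a not in ("E", "C")]
            chars[h] = repl[int(rng.integers(len(repl)))]
    raise RuntimeError("could not scrub motifs")


def _make_decoy(
    rng: np.random.Generator, length: int, detect: DetectionParams
) -> str:
    """Random protein with neither motif in its detection window."""
    for _ in range(MAX_DECOY_DRAWS):
        seq = _random_sequence(rng, length)
        rec = ProteinRecord("decoy", "tmp", seq)
        exxr, cxg = scan_motifs(rec, detect)
        if not exxr and not cxg:
            return seq
    raise RuntimeError(f"no motif-free decoy found in {MAX_DECOY_DRAWS} draws")


def make_dataset(config: SynthConfig) -> SynthDataset:
    """Generate a complete labelled dataset in memory.

    Per species: a Poisson-distributed number of P450s mutated from family
    seeds at the configured identity targets, truncated motif-free
    fragments, and motif-free decoys.  Genes are laid head-to-tail on one
    contig per species with intergenic gaps of 200–2000 bp; exactly
    round(bgc_fraction × n_P450_genes) P450 genes, drawn without
    replacement across the whole dataset, are wrapped in cluster intervals
    padded by less than the minimum intergenic gap, so cluster membership
    of every gene is known exactly.
    """
    rng = np.random.default_rng(config.seed)
    detect = DetectionParams(min_full_length=config.min_full_length)
    panel, seeds, anchors = make_panel(config, rng)
    families = sorted(seeds)

    registry_entries = []
    records: list[ProteinRecord] = []
    coords: list[GeneCoordinate] = []
    truth: list[TruthRow] = []
    p450_ids: list[str] = []

    for cls in config.class_labels:
        mean = config.p450_mean_per_species[cls]
        for si in range(config.species_per_class):
            sp = f"{cls.lower()}_sp{si + 1}"
            registry_entries.append(RegistryEntry(sp, cls, f"Synthgenus{cls}"))
            if config.p450_distribution == "constant":
                n_p450 = int(round(mean))
            else:
                n_p450 = int(rng.poisson(mean))
            proteins: list[tuple[str, str]] = []  # (protein_id, sequence)

            for j in range(n_p450):
                fam = families[int(rng.integers(len(families)))]
                target = float(
                    config.identity_targets[
                        int(rng.integers(len(config.identity_targets)))
                    ]
                )
                u, v = anchors[fam]
                seq = mutate_to_identity(
                    seeds[fam], target, rng, protected=(u, u + 3, v, v + 2)
                )
                pid = f"{sp}_p450_{j + 1}"
                proteins.append((pid, seq))
                truth.append(TruthRow(pid, sp, "p450", fam, f"{fam}A",
                                      target, False, ""))
                p450_ids.append(pid)

            n_frag = round(config.fragment_fraction * n_p450)
            for j in range(n_frag):
                fam = families[int(rng.integers(len(families)))]
                cut = int(rng.integers(80, config.min_full_length))
                frag = _scrub_motifs(seeds[fam][:cut], rng)
                pid = f"{sp}_frag_{j + 1}"
                proteins.append((pid, frag))
                truth.append(TruthRow(pid, sp, "fragment", "", "", 0.0, False, ""))

            for j in range(config.decoy_count_per_species):
                length = int(rng.integers(150, 500))
                pid = f"{sp}_decoy_{j + 1}"
                proteins.append((pid, _make_decoy(rng, length, detect)))
                truth.append(TruthRow(pid, sp, "decoy", "", "", 0.0, False, ""))

            # lay genes head-to-tail on one synthetic contig
            contig = f"{sp}_contig1"
            pos = int(rng.integers(1000, 5000))
            for pid, seq in proteins:
                records.append(ProteinRecord(pid, sp, seq))
                gene_len = 3 * len(seq)
                strand = "+" if rng.random() < 0.5 else "-"
                coords.append(
                    GeneCoordinate(pid, contig, pos, pos + gene_len - 1, strand)
                )
                pos += gene_len + int(rng.integers(200, 2000))

    # wrap an exact fraction of P450 genes in BGC intervals
    clusters: list[BGCCluster] = []
    n_in_bgc = round(config.bgc_fraction * len(p450_ids))
    chosen = sorted(
        rng.choice(len(p450_ids), size=n_in_bgc, replace=False).tolist()
    )
    coord_by_id = {c.protein_id: c for c in coords}
    truth_index = {t.protein_id: i for i, t in enumerate(truth)}
    for rank, idx in enumerate(chosen):
        pid = p450_ids[idx]
        gene = coord_by_id[pid]
        sp = pid.split("_p450_")[0]
        pad_left = int(rng.integers(50, 190))
        pad_right = int(rng.integers(50, 190))
        cluster_id = f"{sp}_c{rank + 1}"
        ctype = CLUSTER_TYPES[int(rng.integers(len(CLUSTER_TYPES)))]
        clusters.append(
            BGCCluster(
                cluster_id=cluster_id,
                species_id=sp,
                contig=gene.contig,
                start=max(1, gene.start - pad_left),
                end=gene.end + pad_right,
                cluster_type=ctype,
            )
        )
        t = truth[truth_index[pid]]
        truth[truth_index[pid]] = TruthRow(
            t.protein_id, t.species_id, t.status, t.true_family,
            t.true_subfamily, t.identity_target, True, cluster_id,
        )

    return SynthDataset(
        config=config,
        registry=SpeciesRegistry(entries=registry_entries),
        panel=panel,
        seed_sequences=seeds,
        records=records,
        gene_coords=coords,
        clusters=clusters,
        truth=truth,
    )


def write_truth(truth: list[TruthRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(VERSION_BANNER + "\n")
        fh.write(
            "protein_id\tspecies_id\tstatus\ttrue_family\ttrue_subfamily\t"
            "identity_target\tin_bgc\tcluster_id\n"
        )
        for t in truth:
            fh.write(
                f"{t.protein_id}\t{t.species_id}\t{t.status}\t{t.true_family}\t"
                f"{t.true_subfamily}\t{t.identity_target:g}\t{int(t.in_bgc)}\t"
                f"{t.cluster_id}\n"
            )


def generate(config: SynthConfig, out_dir: str | Path) -> SynthDataset:
    """Generate a dataset and write every pipeline input format to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = make_dataset(config)
    write_fasta(ds.records, out / "proteomes.fasta")
    write_registry(ds.registry, out / "registry.tsv")
    write_reference_panel(ds.panel, out / "panel.fasta", out / "panel.tsv")
    write_gene_coords(ds.gene_coords, out / "gene_coords.tsv")
    write_bgc_table(ds.clusters, out / "bgc_clusters.tsv")
    write_truth(ds.truth, out / "truth.tsv")
    config.to_yaml(out / "config.yaml")
    return ds
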