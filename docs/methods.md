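# Methods

## Scope and model

`cyp-repertoire` implements the desk-scale core of a comparative CYPome
survey: motif-based P450 detection, identity-threshold family/subfamily
assignment against a reference panel, interval-overlap linkage of P450
genes to secondary-metabolite biosynthetic gene clusters (smBGCs), and
per-class summary and conservation statistics. Inputs are standard
multi-FASTA proteomes plus plain TSV tables (species registry, panel
metadata, gene coordinates, cluster intervals); all coordinates are
1-based inclusive.

## Detection

Candidates must carry both diagnostic motifs. The EXXR pattern (`E..R`)
is accepted only in the C-terminal half of the protein, reflecting the
K-helix position; the CxG pattern (`C.G`) only within the last
`cterm_window` residues (default 100) *and* downstream of the chosen EXXR,
encoding the K-helix → heme-loop order without any structural modelling.
Overlapping regex matches are all reported; the most N-terminal EXXR and
the most C-terminal CxG are the canonical hits (a deterministic
tie-break). Proteins shorter than `min_full_length` (default 300 aa — a
deliberate quantification of "short", since typical bacterial P450s are
~400 aa) with neither motif are fragments; anything else failing the
both-motifs rule is rejected. Requiring *both* motifs, not either, is a
design choice: it gives perfect precision on motif-free decoys at the cost
of missing degenerate-motif P450s, a trade-off acceptable for repertoire
counting. This motif/length heuristic deliberately replaces a remote
conserved-domain search so the pipeline is fully self-contained; on real
proteomes it will admit non-P450 proteins that happen to carry both
patterns in-window, which a domain search would reject.

## Percent identity and assignment

Neither the nomenclature convention nor typical survey write-ups pin down
the alignment behind the 40%/55% thresholds. The package fixes: global
alignment (Needleman–Wunsch) with BLOSUM62, affine gaps open 10 / extend
0.5, identity = identical columns / alignment columns (terminal gap
columns included). The denominator is configurable
(`alignment-columns` | `shorter-sequence`) for sensitivity checks.
Arguments are canonically ordered before aligning so identity is exactly
symmetric even when co-optimal tracebacks differ.

Thresholds are strict: identity must *exceed* 40 (55) to join a family
(subfamily); exactly 40.0 founds a new family. Novel families are named
`NEWFAM1, NEWFAM2, …` in processing order; novel subfamilies take the next
unused letter within their family (A…Z, then AA…), mirroring how curators
allocate letters. The panel is augmented with every assigned query, so
membership in a novel family is a *chain* criterion — each member exceeds
40% to some earlier member, not necessarily to all members. Queries are
sorted by (species, protein id) before assignment, so results do not
depend on input order; best-hit ties break to the lexicographically
smaller reference id.

The neighbor-joining tree export uses d = 1 − identity/100 and scikit-bio's
NJ; it is plumbing for visual inspection, not a phylogenetic analysis (no
multiple alignment, no model of sequence evolution).

## Cluster linkage

A P450 links to a cluster when species and contig match and the gene
interval overlaps the cluster interval by ≥1 bp (default) or is fully
contained (optional stricter rule). "Part of a gene cluster" is rarely
quantified in surveys; any-overlap is the permissive, reproducible
default. A gene overlapping two clusters yields two links but one P450 in
all totals. P450s lacking a coordinate row are skipped with a warning
rather than failing the run.

## Summary statistics

With F families, P P450s, S carrier species, B cluster-borne P450s and N
analyzed species per class:

- average P450s = P / S, rounded;
- diversity % = 100·F / (P·S), 2 decimals — the product in the denominator
  makes this a richness index penalizing both large repertoires and large
  cohorts;
- % in BGCs = 100·B / P, rounded;
- % species with P450s = 100·S / N, rounded.

All rounding is half-away-from-zero on exact decimal arithmetic; this mode
reproduces every published rounded cell of the five-class summary table we
use as a regression fixture, whereas banker's rounding is ambiguous at .5.
Classes with zero P450s report zeroed derived fields with an explicit
`undefined` flag instead of raising, so one empty class cannot abort a
multi-class run. Dominant families are reported jointly on ties.

## Conservation structures

Family presence per class is coded 3 (present) / −3 (absent) — the
convention expected by heat-map viewers that color on sign. Rows are
ordered by agglomerative clustering (Euclidean distance, average linkage;
linkage choice is configurable since heat-map tools differ in their
default). Leaf order uses the standard lower-index-first merge ordering,
making the TSV bit-reproducible. Only rows are clustered; class columns
keep their fixed taxonomic order. The Venn partition assigns each family
to the exact subset of classes containing it; the epsilon class is
excluded from the 4-way partition by default (two families make it
uninformative) with a flag to include it.

## Synthetic data generator

The generator emulates the structure the pipeline assumes, at desk scale:

- **Family seeds**: random ~400-aa sequences with EXXR planted in
  [0.55L, 0.8L] and CxG in the last 60 residues, rejection-sampled until
  all pairwise identities are below 30%, so planted families are
  unambiguous (random sequences of this length align at ~15–18% identity,
  so separability almost always holds on the first draw).
- **Members**: seeds mutated by uniform random substitution at non-motif
  positions — no indels by default, so realized identity is controllable —
  with the substitution count adjusted until the *measured* global-alignment
  identity is within ±3 points of the target (discrete substitutions, and
  gap-tolerant alignment at low identity, make exact targets unreachable).
  Motif anchor residues (E/R, C/G) are never mutated, so every planted
  P450 remains detectable by construction.
- **Fragments**: seed prefixes truncated below `min_full_length` with all
  motif instances scrubbed.
- **Decoys**: random proteins rejection-sampled (bounded at 10,000 draws)
  to contain neither motif within its detection window.
- **Geometry**: one contig per species, genes laid head-to-tail with
  200–2000 bp intergenic gaps; exactly `round(bgc_fraction × n_P450_genes)`
  P450 genes (drawn without replacement dataset-wide) are wrapped in
  cluster intervals padded by 50–190 bp — less than the minimum gap, so a
  cluster can never accidentally cover a neighbouring gene and truth-table
  membership is exact.

Default study conditions: five classes, six species per class, per-species
P450 counts Poisson with class means (Alpha 4, Beta 2, Gamma 2, Delta 14,
Epsilon 1) mirroring the published per-class averages; five seed
families; member identities planted at {60, 80}%; 10% fragment fraction;
10 decoys per species; 20% of P450 genes in clusters. A `constant`
count mode replaces the Poisson draw where exact per-species counts are
needed (e.g. the one-P450-per-species epsilon-like configuration).
Generation is byte-deterministic under a fixed seed.

What the generator does **not** emulate: phylogenetic correlation between
members (mutations are independent), indel variation (optional only),
compositional bias, paralog clustering on the genome, or multi-contig
assemblies. Perfect detection precision/recall on synthetic data therefore
demonstrates the screen's logic, not its performance on real proteomes,
where motif degeneracy and fragmentary gene models blur both boundaries.

## Numerical and testing choices

Tests pin the published five-class summary table's derived cells as exact
regression values, check assignment against a brute-force all-pairs oracle
on random instances (≤8 refs × ≤8 queries; these use ~150-aa sequences to
keep hundreds of instances cheap), and measure ≥95% label-recovery rates
on 200-query cohorts at planted identities 30/60/80% (seed 1234). The ±3
identity tolerance means a 60% cohort realizes 57–63%: above the 55%
subfamily threshold throughout, so family- and subfamily-recovery coincide
there; the 30% cohort realizes ≤33%, safely below the 40% family
threshold. Runtime is kept to minutes by the instance sizes above, chosen
as the smallest scales at which every rule (augmentation, ties, novel
naming) is exercised.

## Known limitations

- The motif heuristic is a stand-in for domain-level evidence; on real
  data it should be treated as a first-pass filter.
- Novel-family formation is greedy and order-canonicalized, not a global
  clustering; different query cohorts can partition the same sequence
  space differently, as manual curation also would.
- The published delta-class cluster table sums near but not exactly to its
  summary-row total (66 vs 69 over 36 vs 37 families as printed); the
  package's consistency checks pin only the columns that reconcile
  exactly (alpha, beta, gamma).
- Identity is pairwise-global; domain-swapped or fused proteins will score
  misleadingly low.
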