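# Methods

This note records the models, conventions and parameter choices behind
`vncatlas`, and what the synthetic-data tests do and do not demonstrate.

## Data model

The canonical container is a sparse cells × genes integer count matrix with
unique cell barcodes and unique gene accessions plus possibly non-unique
display symbols. Gene references resolve accession-first, then by unique
symbol; an ambiguous symbol raises an error listing candidates rather than
guessing — mosquito annotations reuse symbols, and silent misresolution
would corrupt every downstream marker call. Duplicate barcodes are an
error, not a deduplication opportunity: they signal an upstream integrity
problem. Derived layers (`lognorm`, `scaled`, `imputed`) always share the
count matrix shape; per-cell annotations (cluster, phase, chemotype) live
in a metadata table keyed by barcode; every operation appends to a
provenance log.

On disk the 10x triple stores genes × cells; it is transposed at read time
because every statistic here is per-cell. Round trips are integer-exact.

## QC

Cell filters use strict removal inequalities, so boundary values are kept
(a cell at exactly 18% mitochondrial counts survives). The
`log(genes)/log(UMIs)` ratio is base-invariant and undefined (treated as a
violation) for cells with ≤ 1 UMI — such cells fail the UMI floor anyway.
Filters run in the order: cell rules → gene rules → doublet hook; cell
metrics are not recomputed after gene filtering, matching the standard
single-pass pipeline. Doublet calling is a pluggable hook defaulting to
identity, because it is an external algorithm with its own tuning; the
generator can plant doublets for testing custom hooks. Mito/ribo/heat-shock
membership always comes from the catalog file — mosquito gene names have no
universal prefixes that would justify hard-coding patterns.

## Normalization, HVG, scaling, clustering

Normalization is `ln(1 + 10⁴ · x / N_c)`. HVG ranking follows the
variance-stabilizing approach: a lowess trend of log10 variance on log10
mean (statsmodels, locally linear, span 0.3 — a deliberate, documented
variant of the locally quadratic loess some toolkits use) predicts each
gene's expected SD; counts are standardized against it, clipped at √n, and
genes ranked by the clipped values' sample variance, ties broken by gene id.
Scaling uses the population (1/n) SD so test expectations are exact;
constant genes scale to zero.

Clustering is PCA (full SVD — deterministic, sign-fixed) on the scaled HVG
submatrix, an unweighted union k-NN graph (k = 20, a standard default; not
part of the published recipe), and Leiden at the configured resolution with
a fixed seed; labels are relabelled consecutively by descending cluster
size. The reference analysis used 35 PCs at resolution 0.8 for the first
pass and 33 PCs at 1.5 after filtering; PC count stays a config input
because no reproducible elbow/JackStraw rule exists. Removal of
heterogeneous or non-neuronal clusters is an explicit user decision
(`remove_clusters` plus a per-cluster evidence table of mean UMI/gene
counts and marker means), never automated — it was a judgment call in the
original workflow and should stay one.

## Chemotyping

"Expressing" defaults to any nonzero count (lognorm > 0) — the only
parameter-free reading — and is configurable; class fractions are monotone
non-increasing in the detection threshold. GABA = *GAT* ∨ *Gad1* and
Glu = *VGlut* (the main-text marker assignment; an alternative table legend
that swaps these is treated as a transposition error). Strict-ACh mode
drops *ChAT*-only calls because *ChAT* alone over-calls cholinergic
identity in co-expressing cells; strict fractions are provably ≤ default
fractions. Monoamine subtypes (octopamine *Tbh*, serotonin *SerT*,
dopamine *TH*/*Dat*) are annotations, not exclusive classes.

Cluster predominance labels the fast-acting transmitter whose positive
fraction strictly exceeds 0.70. Because flags co-occur within cells, two
classes can in principle both exceed the threshold; the larger fraction
wins and an exact tie yields "none" with a warning. Thresholds below 0.5
are rejected.

Neuropeptide calling requires strictly >25% of a cluster's cells expressing
and mean scaled expression strictly >1.0. The scaled layer is recomputed
over the full gene set on demand so that neuropeptide genes outside the HVG
selection have well-defined z-scores.

## Cell cycle

Module scores are mean lognorm of the set minus mean lognorm of control
genes pooled per set-gene (n_ctrl = 100 draws with replacement from the
gene's expression bin; 24 rank-based equal-size bins). Set genes are *not*
excluded from control pools, so a set equal to its own bin scores exactly
zero. Control draws use a per-set-gene seeded stream, making scores
invariant to gene order. "No detectable cycling programme" is
operationalized as both scores ≤ 0 → G1; otherwise argmax, with an exact
positive tie going to G2M (arbitrary but documented, with a warning).

Composition testing is a Pearson chi-square without continuity correction
on the clusters × phases table; post-hocs are cluster-vs-rest 2 × P tables
with Bonferroni factor = number of clusters. Cluster-vs-rest is one
defensible post-hoc construction among several; note that a strongly
deviant cluster also perturbs every other cluster's "rest".

## Markers

Pre-filters per cluster: fraction expressing within the cluster ≥ 0.5 and
`avg_log2FC ≥ 0.32` (positive markers only), where
`avg_log2FC = log2((mean(expm1 lognorm)_in + 1)/(mean(expm1 lognorm)_out + 1))`
— the +1-pseudocount log2 convention of Seurat-v4-style tables. The 0.32
threshold is interpreted in log2 (≈1.25-fold) and is configurable. The
rank-sum p-value uses the exact conditional permutation distribution of the
mid-rank sum (a subset-sum dynamic programme over doubled mid-ranks, so
ties are exact) when the pooled sample has ≤ 30 cells, and a tie-corrected
normal approximation without continuity correction otherwise; the crossover
keeps the exact path for the toy/oracle regime while cluster-vs-rest
comparisons at atlas scale take the asymptotic path, as standard.
Bonferroni multiplies by the number of genes tested in that cluster.

## Diffusion imputation and correlation

The operator uses an adaptive Gaussian kernel `exp(−(d_ij/σ_i)^α)` with
σ_i the distance to the k-th neighbour, symmetrized as (A + Aᵀ)/2 and
row-normalized. Defaults k = 5, α = 1, t = 3 on 20 PCs mirror the cited
imputation package's documented defaults at desk scale; all are recorded in
provenance. Duplicate cells (σ = 0) take affinity 1 at distance zero.
Imputation is `Pᵗ · lognorm` with integer t (t = 0 is the identity;
exponentiation by squaring). Correlation ranking reports signed Pearson
(Spearman available — the metric used for the original co-expression table
is not recorded, so it is a flag, not a guess), sorts by |cor| with ties
broken by gene id, and flags zero-variance genes with cor = 0.

## Cytometry

CTCF = integrated density − area × mean background; negative values are
legal (signal below background) and flagged. The low/medium/high TH classes
use breakpoints 15,000 and 50,000; the published wording leaves the exact
boundary values unassigned, and assigning them to "medium" is the only
gap-free completion. Image y increases toward posterior ("anterior is up");
a `flipped` flag covers the opposite convention. Posterior fractions use
ROI centroids.

## Synthetic data

Counts are gamma–Poisson: gene g in cell c has mean
`lib_c · base_g · multipliers`, with log-normal library factors
(σ = 0.25) and NB size θ = 2 — the minimal model reproducing scRNA-seq
sparsity and overdispersion. Default conditions, chosen once: 2000 cells ×
300 genes at ~2000 mean UMI, a 43/33/19/5% ACh/GABA/Glu/monoamine mix (the
small monoaminergic class keeps all ten marker genes expressed somewhere,
as in real atlases), marker baseline 0.005 per cell with ×2000 induction
(mean ≈ 10 in expressing cells) so that recovery error is binomial rather
than dropout-limited, and 20-gene per-type identity programmes (×6) that
give clusters a multivariate signature. Phase programmes (70/15/15
G1/S/G2M, 20 genes per set, ×15) and neuropeptide programmes (NP01 in the
monoaminergic type, NP02 in GABA) are planted the same way. QC failures are
constructed against desk-scaled thresholds (100 genes / 500 UMI /
log-ratio 0.6; a healthy 300-gene cell sits near log(250)/log(2000) ≈ 0.73,
so the full-scale 0.8 ratio would reject everything at this matrix size);
percentage rules keep their standard values. Failure modes boost or
restrict exactly the statistic they target, though correlated ratio rules
(low gene count also lowers the log-ratio) can co-trigger — the rejection
report attributes all of them.

What the generator does **not** emulate: batch effects, ambient RNA,
gene-length or GC biases, realistic gene-gene correlation beyond the
planted programmes, and full-transcriptome scale. Passing recovery tests
therefore demonstrates the *rules* are implemented correctly and are
recoverable under the stated noise model — not that the thresholds are
optimal for any particular real dataset.

Known limitation: with only 300 genes, module-score control bins
necessarily contain some phase genes, which blunts the G1 default — planted
cycling cells are recovered essentially completely (and never called G1),
but ~30% of non-cycling cells leak into S/G2M at the default conditions.
At real-data scale (≈12k genes) this contamination vanishes.

ROI tables draw CTCF targets per class (5k/30k/80k ± Gaussian noise) and
back-compute integrated density from drawn areas and backgrounds, so the
CTCF computation is exercised end to end.

## Pipeline

Stages exchange artifacts through one output directory (10x triples and
CSVs), so each is independently rerunnable; a missing prerequisite names
the stage that produces it. One global seed fans out per stage as
`crc32(stage_name) XOR seed mod 2³¹`. `report.json` is written with sorted
keys and floats rounded to 6 decimals, making identical runs byte-identical.
Problem sizes in the acceptance script (400–2000 cells per stage) are the
package's standard desk-scale demonstration conditions.
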