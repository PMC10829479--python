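# vncatlas

Quality control, clustering support and **chemotyping** for single-cell
RNA-seq atlases of the insect ventral nerve cord (VNC), built around the
analysis conventions of mosquito (*Aedes aegypti*) larval CNS data. The
package covers the computational stages between a raw 10x-style count
matrix and the biological readouts of a VNC atlas:

- **QC filtering** — cells are kept when `n_gene ≥ 500`, `n_UMI ≥ 1000`,
  `log(n_gene)/log(n_UMI) ≥ 0.8`, mitochondrial fraction ≤ 18%, ribosomal
  fraction in [5%, 40%] and heat-shock fraction ≤ 5%; genes need ≥ 5 total
  counts in ≥ 2 cells. Every removal is attributed to the rules it violates.
- **Normalization / HVG / scaling / clustering** — `ln(1 + 10⁴·x/N_c)`
  normalization, variance-stabilizing feature ranking, per-gene z-scores
  (population SD), PCA and seeded Leiden community detection on a k-NN graph.
- **Neurotransmitter chemotyping** — per-cell calls from marker detection
  (ACh: *VAChT* ∨ *ChAT*; GABA: *GAT* ∨ *Gad1*; Glu: *VGlut*; monoamines:
  *Vmat*, with *Tbh*/*SerT*/*TH·Dat* subtype annotations), co-expression
  histograms, and the >70% cluster-predominance rule.
- **Neuropeptide cluster calling** — a neuropeptide gene is assigned to a
  cluster when expressed in >25% of its cells with mean scaled (z-scored)
  expression >1.0 (both strict).
- **Cell-cycle scoring** — S and G2/M module scores against
  expression-matched control genes; cells with both scores ≤ 0 default to
  G1; Pearson chi-square (no continuity correction) with cluster-vs-rest
  Bonferroni post-hocs for phase composition.
- **Marker detection** — per-cluster Wilcoxon rank-sum on log-normalized
  values with `min.pct = 0.5` and `avg_log2FC ≥ 0.32` pre-filters
  (`avg_log2FC = log2((mean(expm1 x)_in + 1)/(mean(expm1 x)_out + 1))`),
  Bonferroni-adjusted. The rank-sum p is exact (tie-aware enumeration) for
  small comparisons.
- **Diffusion imputation + correlation ranking** — a MAGIC-style
  row-stochastic operator (adaptive Gaussian kernel on k-NN distances in PC
  space, symmetrized, row-normalized) smooths expression as `Pᵗ·X`; genes
  are then ranked by |cor| with a target gene (e.g. *SerT*).
- **Cytometry** — `CTCF = IntDen − Area × mean background` on ROI tables,
  trimodal low/medium/high classification at 15,000/50,000, and
  anterior–posterior position fractions within a ganglion frame.
- **Synthetic data** — a seeded gamma–Poisson (negative binomial) generator
  that plants cell types, QC failures, cell-cycle programmes, neuropeptide
  programmes and doublets with full ground truth, so every stage is testable
  without downloads.

## Worked example

```python
from vncatlas.chemotype import classify_cells, cluster_predominance
from vncatlas.preprocess import log_normalize
from vncatlas.simulate import CellType, SimConfig, generate

types = (CellType("ACh", 0.45, ("VAChT", "ChAT")),
         CellType("GABA", 0.35, ("GAT", "Gad1")),
         CellType("Glu", 0.20, ("VGlut",)))
ds, truth = generate(SimConfig(n_cells=2000, seed=2, cell_types=types))
log_normalize(ds)
flags = classify_cells(ds, truth.catalog)
for cls in ("ACh", "GABA", "Glu"):
    print(cls, round(100 * flags[cls].mean(), 1))
```

prints

```
ACh 45.6
GABA 35.9
Glu 19.9
```

— the per-cell marker-based classification recovers the planted 45/35/20%
transmitter mix to within sampling error. `examples/` contains one short
script per capability (QC, chemotyping, cell cycle + markers, imputation,
cytometry, full pipeline) that prints its results and what they mean.

## Command line

```bash
vncatlas all --seed 11 --outdir run1        # simulate → QC → ... → report.json
vncatlas qc --outdir run1                   # rerun one stage against the same artifacts
```

Stages exchange artifacts (10x triples, CSVs) through the output directory;
`report.json` collates cell counts at each filter, class fractions, the
predominance table, neuropeptide calls and phase composition. The same
config and seed reproduce `report.json` byte for byte.

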