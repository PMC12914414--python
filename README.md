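# transplast

Analysis pipeline for transcriptional plasticity of bone-marrow stromal
progenitor cells under switching osteogenic/adipogenic differentiation
cues — the setting where cells committed to one lineage (e.g. adipocytes)
are exposed to the opposing lineage's inducers and trans-differentiate.

The package implements, as reusable and tested components:

- **Lineage-signature scoring** — the score of a cell, nucleus or bulk
  sample for a gene signature *S* is the summed z-scaled expression
  `score_u = Σ_{g∈S} (x_gu − μ_g)/σ_g`, with per-gene moments taken over
  the merged unit set; joint osteoblast/adipocyte thresholds classify
  dual-signature and refractory (signature-retaining) cells.
- **Bulk differential expression** — median-of-ratios size factors
  (`s_j = median_g count_gj / (Π_k count_gk)^{1/n}`, rescaled to geometric
  mean 1) and a negative-binomial Wald test with method-of-moments
  dispersion shrunk toward a mean–dispersion trend.
- **Pseudotime trajectories** — deterministic graph ordering (PCA → kNN →
  shortest path from the root population, kNN-smoothed, min–max rescaled
  per library), spline Poisson likelihood-ratio tests for pseudotime
  differential expression (`p < 0.001`, expressed in ≥10% of cells), and
  equal-cell-count binning (100 bins for heatmaps, 5 for projection) with
  per-gene Pearson correlation between direct- and trans-differentiation
  trajectories.
- **Bulk ↔ single-cell integrative PCA** — principal components fitted on
  centered/scaled bulk log expression of the pseudotime-dynamic gene set;
  binned single-cell profiles are standardised with the *bulk* per-gene
  mean and SD and multiplied by the rotation matrix, placing both assays
  in one component space.
- **Interconversion-response classification** — genes induced in the
  target 3-day contrast (padj < 0.01, log2FC > 0) are split into Common
  vs Spec by the opposing contrast (padj < 0.05, log2FC > 0) and
  subgrouped more/similar/less by k-means on {undifferentiated, direct,
  switched} profiles; enhancers are linked to the nearest TSS and group
  differences of DNase/MED1 tag-density changes are quantified by
  Cohen's d — the readout for enhancer priming during opposing-lineage
  prestimulation.
- **A synthetic-data generator** producing all of the above inputs with
  known ground truth: negative-binomial counts driven by logistic
  gene-program activation under arbitrary inducer schedules, refractory
  subpopulations, planted doublets, mitochondrial/library-size variation,
  and an enhancer landscape with plantable priming effects.

## Worked example

One command simulates a five-library single-cell design (undifferentiated,
7 d osteogenic, 7 d adipogenic, and both 7 + 4 d switch libraries), a bulk
companion design and an enhancer landscape, then runs QC → DE → scoring →
trajectories → projection → enhancer classification:

```bash
transplast demo --out-dir demo_out --seed 1
```

which ends by printing the evaluated pipeline properties
(`demo_out/metrics.json`):

```json
{
  "doublet_auroc": 0.9698,
  "kmeans_response_recovery": 0.9737,
  "median_r_ob_genes": 0.4156,
  "priming_cohens_d_dnase": 0.6884,
  "qc_n_cells": 3150,
  "qc_n_kept": 3140,
  "self_projection_max_rel_err": 2.06e-15,
  "terminal_pc1_gap_frac": 0.0013
}
```

Reading these: 3140 of 3150 droplets pass the mito < 10% / genes > 200
filter; the simulated-doublet kNN score separates planted doublets from
singlets with AUROC 0.97; projecting the bulk matrix through its own PCA
environment reproduces the stored scores to machine precision; the
terminal bins of the direct and trans-differentiation trajectories land
within 0.13% of the bulk PC1 range of each other (the two routes converge
to the same osteoblast state); k-means recovers 97% of the planted
more/similar/less interconversion-response labels, and enhancers of
"more"-responding genes show a Cohen's d ≈ 0.69 higher DNase tag-density
gain during opposing-lineage prestimulation than those of "less" genes —
the enhancer-priming signal. (`median_r_ob_genes` is modest in this small
demo because 100-bin profiles from ~600-cell libraries are noisy; the
full-scale trajectory-concordance evaluation below reaches ≈ 0.95.)

Every stage is also a subcommand (`simulate`, `qc`, `de`, `score`,
`trajectory`, `project`, `enhancers`) operating on the TSV/MatrixMarket
files the previous stages wrote, and a Python API mirrors it
(`transplast.qc`, `transplast.de`, `transplast.trajectory`, ...).

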