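# Methods

This note documents the models, estimators and numerical choices behind
`transplast`, and what the synthetic-data generator does and does not
emulate. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself recompute.

## Synthetic-data model

**Gene programs and activation kinetics.** Genes belong to one of six
programs: osteoblast-induced, adipocyte-induced, adipocyte-repressed,
commonly induced, stem-cell, or null. Each program responds to a set of
driving inducers (`ob`, `ad`, or both; the stem program responds to both
with negative sign). Along an inducer schedule, a program accumulates net
exposure *E* at +1 day per day under a driving inducer and loses it at
`decay_rate` (default 2.5) days per day otherwise, floored at zero.
Activation is a normalised logistic in *E* with midpoint 1.5 d and
steepness 0.6 d, so ~3 days of exposure essentially completes induction.
The asymmetric decay reflects the rapid collapse of a lineage program once
its inducers are withdrawn: after a 7-day commitment plus 4-day opposing
switch, the old program is fully off and the new one is within ~2% of the
direct-differentiation level — direct- and trans-differentiated
populations converge to the same terminal state, while a symmetric decay
would leave the old program ~60% active, contradicting the phenomenon the
pipeline is built to analyse.

**Counts.** A unit's expected library size is its depth (lognormal; bulk
≈ 4×10⁵, cells ≈ 5×10³). Per-gene means are depth × share, where shares
are baseline lognormal weights (σ = `weight_sigma`, default 1) multiplied
by 2^(logfc_scale · sign · activation) and renormalised to sum to one.
The renormalisation makes "null" genes genuinely flat along a trajectory;
without it every null gene inherits a compositional trend from the
library-size constraint, which would contaminate calibration checks.
Residual compositionality (induced genes diluting others' shares) is
still present and is absorbed by median-of-ratios normalisation, as in
real data. Counts are negative binomial with var = μ + αμ²
(α = 0.1 for bulk, 0.05 for droplet/UMI data, which is near-Poisson).

**Single-cell libraries.** Cells sit at t ~ Uniform[0, 1] along the
*final* inducer segment, with earlier segments completed — libraries are
harvested after the full protocol, so asynchrony spreads a switched
library's cells along the conversion path, never back to the
undifferentiated state. Refractory cells (default 10% of switch-library
cells) experience the first inducer for the whole duration, reproducing
the subpopulation that retains the initial lineage's signature. Doublets
(default 5%, appended and flagged) are random pair sums binomially thinned
to 1.8× a single-cell depth. A dedicated `MT-` gene block receives a
per-cell mitochondrial fraction (Normal(0.05, 0.02), clipped) for QC.

**Interconversion response.** Every lineage-induced gene carries a planted
more/similar/less label (balanced thirds). In a switch-into-lineage
schedule the gene's log2 effect gains ±`response_logfc` (default 1) times
its activation. The single-cell factory defaults this modifier to zero so
direct and switched libraries share their terminal state exactly; the
bulk interconversion design keeps it on.

**Enhancer landscape.** One pseudo-chromosome (`chrS`, 0-based half-open
BED), genes every 10 kb, 1–3 enhancers per gene placed within ±4 kb of
their own TSS (so nearest-TSS linking is exact by construction). DNase and
MED1 tag densities are lognormal (median 10, σ = 0.5); a gene's own-lineage
3-day condition doubles its enhancers' tags. Enhancers of "more" genes
additionally receive `delta_prime` (default 10) tags in the
opposing-lineage 3-day condition — a planted priming effect of ≈ 0.9
pooled SD on the log2 prestimulation change, sized so it remains clearly
detectable (d ≥ 0.5) after classification noise, while `delta_prime = 0`
yields |d| < 0.2.

**Not emulated:** read-level artefacts (FASTQ, UMI collapsing), ambient
RNA, batch effects between libraries, branching lineage decisions, and
real enhancer–gene regulatory structure beyond nearest-TSS proximity.
Passing tests therefore demonstrate correct recovery of the planted
generative structure, not robustness to these real-data features.

## Analysis stages

**QC.** Per-cell totals, detected genes, mitochondrial percentage; the
droplet filter keeps cells with mito % strictly below 10 and detected
genes strictly above 200. The doublet score co-embeds observed cells with
an equal number of simulated pair-sum doublets in 20 PCs of log1p
counts-per-10k expression and reports the simulated fraction among k = 30
nearest neighbours, rescaled by the simulation ratio. Scores are reported,
not filtered on — except in the trajectory stage, where cells scoring
≥ 0.6 are dropped before graph construction: a heterotypic doublet is a
convex combination of two distant states and acts as a shortcut edge that
can reorder or even invert a shortest-path pseudotime.

**Bulk DE.** Median-of-ratios size factors over genes with nonzero counts
in all samples, rescaled to geometric mean one. The Wald test estimates
per-gene dispersion by method of moments on normalised counts (pooled
within-group variance), floors it at 10⁻⁸, and shrinks it 50/50 toward a
fitted a₀ + a₁/μ trend; log2FC uses group means with pseudocount 0.5; the
standard error comes from the delta method under var(k/s) = μ/s + αμ²;
p-values are two-sided normal. All-zero genes get NA. This is a
deliberately simple test — its acceptance surface is calibration
(type-I ≈ 0.05 at 6 vs 6, α = 0.1) and recovery of planted effects, not
identity with any particular production DE tool. Known limitation: with a
large fraction (≳20%) of one-sided DE genes and high dispersion, the
median-of-ratios factors absorb part of the effect (mixture-median shift),
attenuating estimated fold changes; the evaluation designs plant a 5%
DE fraction, which keeps this bias ≲ 0.05 log2 units.

**Signature scoring.** Genes are z-scaled across the merged unit set
(cells: after log1p counts-per-10k, clipped at ±10; bulk: no clip);
zero-variance genes are dropped and reported. A signature score is the
sum of scaled values over the signature∩matrix genes (intersection size
logged). Dual-signature classification thresholds default to the 90th
percentile of each score in the undifferentiated reference library; ties
classify above.

**Pseudotime.** log1p cp10k → top 20 PCs → symmetric kNN graph (k = 15,
Euclidean) → Dijkstra distance from the cell nearest the root population's
centroid. Raw shortest-path distances accumulate independent per-hop
noise, so two rounds of averaging over each cell's own kNN (self included)
are applied before the per-library min–max rescale to [0, 1]; using each
cell's own neighbourhood keeps duplicated cells at identical t.
Disconnected cells get the distance of their nearest connected cell plus
the maximum edge weight, and are flagged. The direct trajectory is rooted
in the undifferentiated library; the trans-differentiation trajectory is
rooted in the committed (pre-switch) lineage's library and its graph
contains only that library and the switched one.

**Pseudotime DE.** Natural cubic spline basis (df = 3: boundary knots at
the t range, two internal quantile knots) in a Poisson log-linear model
with log total counts as offset, fitted by batched IRLS (25 iterations,
η clipped at ±30, 10⁻¹⁰ ridge); LRT against the offset-only null with p
from χ²(3). Genes expressed in < 10% of cells are excluded (NA). The test
is exactly calibrated under Poisson noise; under NB overdispersion it is
anticonservative in proportion to 1 + αμ, which the p < 0.001 threshold
and expression filter mitigate — a property shared by any Poisson LRT on
overdispersed counts.

**Binning and concordance.** Cells sorted by (t, cell id) are cut into
contiguous equal-count bins (remainder to the earliest bins; an
equal-width scheme is available but empty bins are an error). Per-gene
Pearson r between two binned profiles is computed over paired bin means;
zero-variance genes give NA; output is ranked descending. Significance
groups (direct-only / switch-only / both) partition the union of
significant genes.

**Projection.** Bulk log2(normalised + 1) expression of the dynamic gene
set (union of genes with adjusted p < 0.001 in any pseudotime DE result)
is centered and scaled per gene; components come from SVD with a
deterministic sign convention (largest-|loading| entry positive). Binned
single-cell profiles of log1p cp10k expression are standardised with the
*bulk* moments and multiplied by the rotation; model genes missing from a
profile are imputed at scaled 0 (the bulk center), allowed down to 80%
coverage. Self-projection of the bulk matrix reproduces its scores to
floating-point accuracy by construction, and this identity is asserted.

**Response classification and priming.** Induced = padj < 0.01 and
log2FC > 0 in the target 3-day vs undifferentiated contrast; Common adds
padj < 0.05 and log2FC > 0 in the opposing contrast. k-means (k = 3,
50 restarts, fixed seed) runs on row mean-centered 3-condition profiles;
clusters map to more/similar/less by their mean switched-minus-direct
contrast. Row centering (not z-scoring) keeps labels invariant to a
gene's absolute expression level without inflating noise for flat
profiles — per-row variance scaling divides the "similar" archetype's
noise by a near-zero SD and caps recovery well below what the planted
separation supports. Enhancers pass a MED1 > 0 floor, link to the gene
with the nearest TSS by midpoint distance (ties: smaller TSS coordinate,
then lexicographic gene id; no cross-chromosome links), and group
differences of log2 tag changes (pseudocount 1; precomputed fold-change
columns pass through) are summarised by Cohen's d with pooled SD
(d = NA when the pooled variance is zero, 0 when additionally the means
agree).

## Evaluation designs and problem sizes

The evaluations in `transplast.evaluation` (used by the tests and the
reproduction script) fix these designs:

- *Size factors*: 4 samples with planted depths 0.5/1/2/4 × 4×10⁵,
  5000 null genes.
- *DE calibration*: 2000 null genes, 6 vs 6, α = 0.1; recovery/power on
  100 genes planted at log2FC = 2 among 2000 (a 5% DE fraction, keeping
  the normalisation bias small; see above).
- *Pseudotime recovery*: 1000 cells along an undifferentiated→osteoblast
  trajectory with slow, non-saturating kinetics (midpoint 3.5 d,
  steepness 1.5 d) and strong programs (logfc_scale 3), so the latent is
  informative over its whole span; a fully differentiated library serves
  as the terminal-state root for the reversal check.
- *Spline-LRT calibration*: 2000 planted-null genes, 1000 cells, Poisson
  noise (the model's own null); power on 300 sigmoid genes of 2-log2
  amplitude at the default UMI dispersion.
- *Trajectory concordance*: direct 7 d and switched 7 + 7 d osteogenic
  arms (equal final-segment duration, so both arms traverse the same
  program kinetics), 2500 cells/library, logfc_scale 3, weight σ 0.7,
  100 bins, median r over the planted osteoblast program.
- *Significance-group comparison*: same design at 900 cells/library and
  logfc_scale 0.7 (marginal power), spline tests fitted on every 4th cell
  with profiles binned from the rest, averaged over 5 replicates — group
  membership is then independent threshold luck, which is the claim under
  test.
- *Response/priming*: the 3-day interconversion bulk design with 6
  replicates; priming evaluated end-to-end (DE → classification → k-means
  → linking → Cohen's d) at delta_prime 10 and 0.

The end-to-end demo runs at 600 cells/library and 2000 genes, chosen as a
desk-scale rendition of the study design (whose libraries had thousands of
cells per condition and genome-wide genes).

## Known limitations

- The Poisson spline LRT is anticonservative under strong NB
  overdispersion (see above); a negative-binomial LRT would calibrate
  better at the cost of per-gene dispersion estimation along pseudotime.
- Shortest-path pseudotime assumes a single unbranched trajectory per
  graph; branching fates need a different method.
- Nearest-TSS linking ignores strand, gene bodies, and long-range
  regulation; with the generator's spacing it is exact, on real annotation
  it is the usual proximity heuristic.
- Trajectory comparisons between arms with very different final-segment
  durations compress one arm's dynamics into a sub-interval of pseudotime,
  bounding the attainable per-gene correlation below 1 even without noise.
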