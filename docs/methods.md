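# Methods

## The measurement model

One well of a 384-well plate holds cells transfected with an siRNA pool
against one gene. After irradiation, imaging yields per-cell pairs
(DNA-stain intensity, foci count). The pipeline models the well readout —
mean foci per S/G2 cell — as

    readout[r, c, p] = μ + α_r + β_c + γ_p + gene effect + noise,

an additive decomposition into an overall level, systematic row, column
and plate biases (evaporation edges, dispenser gradients, staining
batches), the biology of interest, and counting noise. Everything
downstream follows from how each term is estimated.

## Cell-cycle gating

Recombination foci form almost exclusively in S/G2, so G1 cells dilute
the readout. All cells of one replicate run are pooled (one gating curve
per run: pooling across plates keeps every quantile bin well populated,
and per-plate curves would be under-sampled), sorted by DNA intensity,
and split into `n_bins = 50` equal-count bins. Quantile bins rather than
equal-width bins keep the G1 peak — which dominates a DNA-content
histogram — from starving the S/G2 region of resolution. The cut-off is
the linearly interpolated intensity between the centers of the last bin
with mean foci below the target level (default 2 foci) and the first bin
at or above it, scanning upward; a first-crossing rule with no smoothing,
because bin size already averages several hundred cells. Cells exactly at
the cut-off are retained (≥), a deterministic tie rule. If the curve
never reaches the level the cut-off is reported absent and gating fails
loudly rather than silently passing everything.

Because bin centers are within-bin mean intensities and the interpolation
is linear, the estimate is exactly equivariant under positive affine
rescalings of the intensity axis (and approximately so under any strictly
monotone rescaling); the property test covers the affine case.

Wells are summarized by the arithmetic mean foci count over gated cells
(median and fraction-of-positive-cells are selectable alternatives — the
field uses all three and the original choice is not documented in the
screens this design follows). Wells with fewer than `min_cells = 20`
gated cells are reported missing rather than noisy. Control separation is
summarized per plate by negative/positive means, a pooled-variance t
statistic and SSMD, flagging any plate in which the positive control
(knockdown of the focus-forming protein itself) fails to reduce foci.

## 3D B-score normalization

The classical B-score polishes each plate separately. Here the plate
stack is polished jointly: the readouts form a row × column × plate cube
and a three-way median polish estimates α, β, γ from the whole screen,
which makes the row/column estimates far more robust and captures
plate-to-plate variation as a vector of plate effects in the same fit.

Implementation choices:

- **Sweep schedule.** Rows, then columns, then plates; each sweep
  subtracts the median (over observed cells) of the current residuals
  along that axis and accumulates it into the corresponding effect.
  After every full iteration the median of each effect vector is
  re-absorbed into the overall term, keeping the decomposition identified
  (each effect vector has median ≈ 0). Tukey's two-way convention,
  generalized; an independently coded plain-loop oracle pins the
  behaviour in the tests.
- **Stopping.** When the total absolute adjustment of an iteration falls
  below `tol` × (total absolute data), or at `max_iter` (default 20,
  `tol = 1e-6`). Median polish converges geometrically but can need
  hundreds of iterations for residual medians below 1e-6; analyses that
  require fully polished residuals raise `max_iter` (the acceptance
  checks use 3000 with `tol = 1e-13`, still fractions of a second for
  a screen-sized cube).
- **Missing wells.** Medians are taken over observed entries only;
  structurally empty rows/columns (e.g. the empty outer plate columns)
  are dropped from the cube before polishing, and a slice with no
  observations at all raises instead of silently emitting zeros. Even
  counts use midpoint medians.
- **Controls are masked.** Control wells are systematically shifted by
  design; leaving them in would bias the medians of their rows/columns.
  An `include_controls` mode exists for sensitivity analysis.
- **Scaling.** Residuals are divided by 1.4826 × MAD computed over all
  observed residuals of the whole cube — one screen-wide scale, because
  the plate-to-plate variation is already estimated by the plate effects
  and a per-plate scale would reintroduce it (a per-plate mode is
  available). 1.4826 = 1/Φ⁻¹(3/4) makes the scale a consistent
  estimator of the SD under normality, so a score of −2 reads as "two
  SDs below the screen level". Zero MAD (degenerate data) yields all-zero
  scores with an explicit flag.

Genes measured in several wells collapse by the median of their well
scores. A naive per-plate z-score (`zscore_baseline`) is included solely
as the comparison baseline for the artifact-removal tests.

## Hit calling and replicate merging

Each replicate's gene scores are ranked ascending (most suppressive =
rank 1, average ranks at ties) and the two ranks summed; the merged list
orders by rank sum, with ties broken by mean score (more negative first)
then lexical gene id, for fully deterministic output. Genes scored in
only one replicate are excluded from merging — a rank sum is undefined
for them — and reported separately.

The candidate-list size is chosen by computing the Pearson correlation
(Spearman selectable) between the replicates' scores over the top N
merged genes for N = 50, 75, 100, …; the first maximum wins. Sizes with
undefined correlation (zero variance) are recorded missing and skipped.

Hits are genes scoring **strictly** below the threshold (default −2).
The composite HRR score is the per-gene product of this screen's score
with an orthogonal screen's score; both the raw product and a
sign-concordance flag are kept, because concordant-negative genes are
candidate suppressors of both readouts while discordant genes (high foci,
low recombination activity) mark late-acting repair factors — both
patterns are informative. Set overlaps against earlier screens are
reported as |A∩B|/|A| with a hypergeometric upper-tail p.

## Network filtering and enrichment

Candidates are mapped onto a weighted functional-association network,
keeping edges with confidence ≥ 0.5; candidates with no qualifying edge
to another candidate drop out as isolated (mirroring the shrinkage of a
candidate list to its network-connected core). The subnetwork is
clustered by a shared-neighbourhood agglomerative procedure: each cluster
carries the element-wise maximum of its members' closed neighbourhood
weight vectors; cluster similarity is the weighted Jaccard of those
vectors; the best edge-connected pair merges while its similarity stays
above a threshold (default 0.3, minimum reported cluster size 3); ties
resolve lexically. Connected components never merge, and the structural
test cases (cliques joined by a bridge, stars) are robust to the
threshold choice. This is a documented shared-neighbourhood variant, not
a re-implementation of any specific published clustering tool, and makes
no claim of cluster-for-cluster identity with results obtained with one.

Enrichment is the standard over-representation test: for a universe of N
genes, K in the set, n candidates and k overlapping, the p-value is
P(X ≥ k) under Hypergeometric(N, K, n) (SciPy's survival function, stable
in log space; an exact combinatorial summation serves as the test
oracle), with Benjamini–Hochberg adjustment across tested sets. The
universe defaults to the screened library, not the genome, because
candidates are drawn from the library; it is overridable. Candidates
missing from the universe are dropped with a logged count.

## The synthetic screen generator

The generator emulates the experiment the pipeline is built for, with
every generative quantity recorded:

- **Geometry.** 20 plates of 16 × 24 wells, outer columns empty, 8
  scrambled negative-control and 8 positive-control wells per plate,
  ~1000-cell seeding emulated as Poisson(cells_per_well = 200); two
  replicate runs share gene effects but draw independent noise and
  artifacts.
- **DNA content.** A lognormal G1 component (mode 100, σ = 0.12), a
  lognormal G2 component at twice the G1 mode, and a uniform S-phase
  bridge (weights 0.55/0.30/0.15) — the shape of a DAPI histogram.
- **Foci curve.** Mean foci per cell is ≈ 0.2 through G1 and rises
  linearly with DNA intensity above 110 at 0.05 foci per unit, so it
  crosses the gating level 2 at intensity 146 — the recorded true
  cut-off. Counts are negative-binomial (dispersion 5; Poisson
  selectable): per-cell counts are overdispersed in real imaging data.
- **Effects and artifacts.** 2% of genes are true hits with foci
  suppressed to 0.3×; positive controls suppress to 0.1×. Artifacts are
  additive on the expected-foci scale — one row vector, one column
  vector and one per-plate offset per run, each N(0, 0.3) — matching the
  additive model the polish assumes (a multiplicative mode exists to
  probe misspecification). 0.3 foci is about one well-mean noise SD at
  the default 200-cells/well depth.
- **Reality gap.** The generator does not model spatially correlated
  artifacts, transfection-efficiency gradients, cell death, siRNA
  off-target effects, or segmentation errors; passing tests therefore
  demonstrate correctness of the statistical machinery under the stated
  model, not robustness to every failure mode of real screens.

A score-level companion (`simulate_score_pairs`) generates duplicate
gene-score maps directly: null genes draw iid standard-normal scores in
each run; hit genes (2%) carry a gene-specific effect drawn uniformly on
−3 ± 1 that both runs observe with residual SD 0.2. The small residual
SD encodes that a genuine suppressor phenotype is highly reproducible
between duplicate runs relative to plate noise; it is also what makes
the replicate-correlation sweep peak at the planted hit count — with
unit-noise hits, the correlation over the top N provably keeps rising
past the true count because the hit/null mean separation contributes a
between-cluster covariance term that maximizes near balanced mixing.

## Test and acceptance problem sizes

The statistical acceptance checks run at reduced scale, chosen so that
100-seed loops complete in minutes on one CPU while every rate bound
retains a comfortable margin (all were validated on held-out seed ranges
before being frozen): artifact-removal and null-calibration screens use
6–12 plates at 80–150 cells/well (with artifact SD 0.45 in the
artifact-removal loop, about one noise SD at that depth); gating loops
use 20 plates at 30 cells/well, since the cut-off estimate pools cells
across a whole run and its error is dominated by how well the plate
artifact means average out; rank-merging loops use the score-level
generator at 10 000 genes. The gating estimate is compared against the
crossing of the run's realized mean-foci curve (the configured curve
diluted by the average knockdown effect and shifted by the run's mean
artifact) — the quantity the estimator actually estimates; the
configured crossing differs from it by a small artifact-dependent offset.

## Known limitations

- The polish's iteration count for fully converged residual medians is
  data-dependent; the default (20) is fine for scoring but not for
  asserting sub-1e-6 residual medians.
- Quantile-bin gating assumes the pooled foci-vs-intensity curve is
  monotone through the crossing region; a strongly non-monotone curve
  (e.g. from segmentation artifacts at high intensity) would need the
  selectable alternatives re-examined.
- The clustering is O(n³) in subnetwork size — fine for candidate lists
  of hundreds of genes, not for whole networks.
- File formats are deliberately minimal (delimited text, GMT); no
  vendor image formats or databases are read.
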