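# Methods

This note documents the models, estimators, and numerical choices behind
`retinodiff`, and what the synthetic data generator does and does not
emulate.

## Data model and preprocessing

The container is `anndata.AnnData`: raw counts in `X` (non-negative
integers, cells × genes), optional `normalized`, `spliced`, `unspliced`
layers of identical shape, cell metadata in `obs` (barcode-keyed), gene
metadata in `var` (case-sensitive symbol-keyed). On disk, Matrix Market
files are stored genes × cells (the 10x convention, 1-based indices) and
re-oriented on read; counts and identifiers round-trip bit-exactly.

QC filters cells first (minimum detected genes; optional cap on the
fraction of counts in the cell's top gene), then genes (minimum detecting
cells) on the retained cells. The order is fixed and reported because it
changes results on edge cases. Defaults (200 genes/cell, 3 cells/gene) are
conventional and overridable; removing every cell is a hard error.

Normalization scales each cell to the median library size and applies
log(1+x). The median target keeps the scale data-driven; zeros and
within-cell ranks are preserved.

**Variable genes (cv-mean).** Per gene, mean and coefficient of variation
are computed on the normalized layer. The CV-vs-mean trend is the per-bin
median over 20 equal-count mean bins, linearly interpolated between bin
centers; the selection statistic is the excess CV *studentized by the
interpolated within-bin MAD*. Studentization matters: raw CV scales
steeply with 1/mean, so without it genes detected in a handful of cells
dominate the ranking regardless of biology. Ties break lexicographically
by symbol, making the selection invariant to cell and gene order.

**PCA.** Genes are centered and unit-scaled, z-scores clipped at ±10 SD to
bound outlier influence, re-centered, and decomposed by SVD. Component
signs are fixed by making each component's largest-magnitude loading
positive. The neighbor graph connects each cell to its k nearest Euclidean
neighbors (brute-force distances, stable sort so distance ties resolve to
the lower cell index) and is symmetrized by union.

## Signature scores, cell cycle, positivity

A signature score is the mean normalized expression of the signature genes
minus the mean over a control pool sampled from matching mean-expression
bins (25 bins, 50 controls per signature gene, seeded RNG, signature genes
excluded from the pool). Bin-matching removes depth and expression-level
confounding, so a random gene set scores ≈ 0. Cycle phase: G1/G0 when both
S and G2/M scores ≤ 0 (threshold configurable), otherwise the larger score;
cycling ⇔ S or G2/M. Positivity is detection-based (raw count ≥ 1 by
default) with Wilson 95% intervals — the score interval stays calibrated at
the extreme fractions typical of late marker genes, which a Wald interval
does not.

Cross-reference mapping scores the top-30 enriched genes of each reference
population on query cells and averages within query clusters; shorter
rankings are clamped with a warning.

## Heterogeneity statistic

For a sample, let λ₁ ≥ λ₂ ≥ … be the PCA eigenvalues of the unit-scaled
expression matrix and F(k) the cumulative explained-variance fraction. The
white-noise baseline F₀(k) is the mean curve over datasets in which each
gene's values are independently permuted across cells — this destroys all
gene–gene correlation while preserving every gene's marginal exactly, so
the contrast isolates correlation structure. The heterogeneity index is
the mean component-wise gap over the first K components (default K = 50,
20 permutations). It is ≈ 0 for independent noise, grows with planted
module strength and with the number of distinct mixed cell types, and on
the bundled time course peaks at intermediate time points.

The index makes ordinal comparisons between samples of similar size; no
formal test is attached to it.

## Markers and the anticorrelation screen

Enriched genes: one-vs-rest Wilcoxon rank-sum per gene per cluster on the
normalized layer (vectorized asymptotic form; the standardized statistic is
used for ranking among genes with positive log2 fold change), BH-adjusted
within cluster. log2 fold changes use pseudocount 1 for bounded behavior at
zero means.

The surface-marker screen keeps genes with mean normalized expression
≥ 0.5, computes each gene's Pearson correlation with the per-cell RPE and
neural-tube signature scores, and ranks ascending by the combined score
(mean of the two correlations; a max rule is available). Genes
anticorrelated with both lineage scores in a mixed culture are progenitor
candidates; intersecting with a user-supplied surfaceome yields sortable
markers. The combination rule is a package decision — the two correlations
are also reported separately.

## Integration and projection

CCA treats the shared genes as observations and the cells of each dataset
as two variable blocks: canonical vectors a, b maximize corr(Xᵀa, Yᵀb)
across genes, after per-gene standardization within each dataset. The
cell-cell covariance blocks are shrunk with a ridge of 0.05·trace(C)·I
before whitening. The strength is deliberate: with cells comparable to or
outnumbering genes, light shrinkage leaves the whitened problem overfitted
(leading correlation saturates at 1 even for independent noise); at
0.05·trace the solution approaches diagonal-covariance CCA, the standard
and robust choice for single-cell integration, and planted shared
gradients are recovered at |r| > 0.95. Reported canonical correlations are
the empirical Pearson correlations of the paired variates (so self-
alignment yields 1 exactly); significance should be judged against a
gene-permutation null, which the test suite demonstrates.

Pseudospace min–max scales a supplied axis (e.g. the leading canonical
variate) to [0,1], orienting it so a user-chosen anchor marker is high at
position 0; per-gene profiles are per-bin means scaled to each gene's
maximum. Label projection uses correlation distance d = 1 − r over shared
genes, majority vote among k = 10 nearest reference cells (ties: smaller
mean distance, then lexicographic label), inverse-distance-weighted
neighbor coordinates for the projected embedding, and flags queries with
mean neighbor distance > 0.9 as low-confidence. k = 1 reproduces
single-nearest-cell assignment.

## Ordinal staging

The classifier is a proportional-odds cumulative-logit model on the
leading principal components of the staged reference (n_features = 50,
capped by rank), with features standardized and a ridge penalty λ‖β‖²
(λ = 1): P(y ≤ j | x) = σ(θⱼ − xᵝ) with strictly increasing thresholds
parameterized as θ₁ plus positive increments. The single latent maturation
score forces misclassifications onto adjacent classes, which is the
behavior an ordinal scale requires. Fitting is L-BFGS on the analytic
gradient; the implementation is cross-checked in the tests against
statsmodels' `OrderedModel` at vanishing ridge. Non-separability is
flagged when the overfitting-adjusted McFadden pseudo-R²
((NLL₀ − NLL − p)/NLL₀) falls below 0.05. Query genes missing from the
basis are zero-imputed (warning above 20%; error above 50% missing).
Models serialize to a single JSON archive.

Default stage classes are W5, W6–8, W9–13, W17–24, Adult; the binning is
configurable, and the gap at W14–16 follows the granularity of available
embryonic references.

## Pseudotime and steady-state velocity

Pseudotime is the diffusion distance from a root cell on the
Gaussian-weighted neighbor graph (kernel bandwidth = median neighbor
distance, so uniform scaling of the embedding is a no-op): the symmetric
normalized transition matrix is eigendecomposed, the stationary component
dropped, coordinates weighted by λ/(1−λ), and distances min–max scaled to
[0,1]. The root is a cell id or the argmax of a signature score (ties to
the lowest index, with a warning). A disconnected graph is an error that
reports the component sizes. Pseudotemporal profiles are binned means
(empty bins filled from the nearest populated bin, with a warning),
moving-average smoothed, and max-scaled per gene.

**Steady-state velocity.** Under du/dt = α − βu, ds/dt = βu − γs, the fixed
point satisfies u*/s* = γ/β, so a line through the origin fitted to cells
at expression extremes estimates γ̂ (in units of β). The estimator
implements the classic recipe with three safeguards that real velocity
tools also rely on, each addressing a specific failure mode of the naive
fit:

1. *Library-size normalization* of both layers (per cell, to the median
   total) — otherwise depth variation masquerades as kinetic state and
   tilts the slope.
2. *kNN pooling* over cells of similar state before fitting (default pool
   ≈ n/15, at least 30). The pooling coordinate for each gene is the
   library size of all *other* genes (a leave-one-out scalar; windows in
   its rank order), so the neighborhoods carry no target-gene counting
   noise.
3. *Cross-fitted selection.* Each pooled neighborhood is split in half;
   one half selects the extreme-quantile cells (bottom and top 5% of
   pooled spliced expression) and supplies the s-weights of the
   origin-constrained fit, the other half supplies the fitted values.
   The two role assignments are averaged. Because the fit is linear in
   the fitted half's noise and that noise is independent of the
   selection, the slope is unbiased — a plain least-squares fit on raw
   counts is attenuated by 10–40% at realistic expression levels, which
   the test suite demonstrates against the closed-form steady state.

Residuals r = u − γ̂·s (on pooled, normalized values) are thresholded at
±tol (default 5% of the gene's maximum pooled unspliced signal): above →
"up", below → "down", within → "steady". Genes detected in fewer than 30
cells are flagged unfitted.

## Synthetic data generator

`simulate_timecourse` draws negative-binomial counts (gamma–Poisson; shared
inverse-dispersion θ = 2, variance μ + μ²/θ) with per-gene lognormal
baselines (median 0.5 counts, log-sd 1 — real transcriptomes span orders
of magnitude, and several estimators, notably bin-matched control scoring,
degenerate if all baselines coincide). Structure on top of the baseline:

- **Composition:** seven ordered time points (hESC, D7 … D60) mixing six
  cell types (pluripotent → neural-fold → retinal progenitor → early/mid/
  late RPE). Diversity expands at intermediate days and collapses onto RPE;
  the late-RPE fraction rises 17.1% → 55.7% → 77.7% over the last three
  time points and the cycling fraction falls from 60% to 5% with a bump
  after the D30 replating.
- **Marker programs:** 30 dedicated genes per type at 8-fold the baseline.
- **Correlated modules:** three 50-gene blocks with log-mean perturbation
  `loading × N(0,1)` per cell (module_strength = 1) — the low-rank
  structure the heterogeneity statistic detects.
- **Cell cycle:** S and G2/M programs (20 genes each) at 6-fold in cycling
  cells and repressed to 0.2× baseline in non-cycling cells. The off-state
  repression mirrors real data (MKI67, TOP2A are near-absent outside the
  cycle) and is what makes a zero threshold meaningful for phase calls.
- **Kinetics:** `simulate_kinetics` draws Poisson counts around the exact
  moments of the splicing ODE — the fixed point (u* = α/β, s* = α/γ) for
  the steady regime, the closed-form transient from (0,0) for induction,
  and the decay from steady state for repression, sampled over three
  slowest time constants (cells beyond that have effectively completed the
  transition). Unit-mean lognormal size factors (sd 0.3) spread cells
  along the phase-portrait diagonal as library-size variation does in real
  data.
- **Ordinal references:** each gene peaks at a random position on the
  maturation axis with a Gaussian bump (width 0.75 stages) of height
  `separation` in log-mean, so adjacent stages overlap more than distant
  ones and `separation` controls class distance (0 = no signal).

What the generator does **not** emulate: batch effects, doublets, ambient
RNA, gene-regulatory-network dynamics, realistic gene-gene covariance
beyond the planted modules, and cross-species effects. Tests passing on
this generator demonstrate correctness of the estimators under the stated
model, not robustness to every artifact of real droplet data.

## Benchmark conditions

The acceptance script and the end-to-end tests run fixed study conditions:
heterogeneity null at 500 cells × 500 genes with 20 permutations (time
course: K = 40, 10 permutations per time point); staging on 5 × 200 cells
at separation 3 with a 20% hold-out; the screen on 2,000-cell
progenitor/RPE/neural-tube mixtures over 20 seeds with a 50-gene
surfaceome; velocity on a 3×3 rate grid α ∈ {20,40,80}, γ ∈ {0.25,0.5,1},
β = 2 (well-detected genes, as phase-portrait analyses use in practice)
inside a 100-gene panel at n = 2,000 cells; label transfer on 5 × 300
cells. These sizes keep a full run around one minute on a single core.

## Known limitations

- The heterogeneity index depends on sample size through the permutation
  baseline; compare indices only across samples of similar cell counts.
- The steady-state velocity estimator assumes genes detected well enough
  to populate both expression extremes; weakly expressed genes (mean
  spliced counts below ~5) carry wide slope uncertainty.
- CCA reports empirical variate correlations, which are optimistically
  biased absolute numbers; use the permutation null for significance.
- The ordinal classifier is a standard proportional-odds model, chosen for
  auditability; it assumes a single dominant maturation axis in the
  reference.
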