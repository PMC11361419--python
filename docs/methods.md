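# Methods notes

This note documents the models, defaults and design choices behind
`redlist-gapfill`, in the order the pipeline runs. It states no empirical
result that the test suite or `scripts/acceptance.py` do not themselves
compute.

## Synthetic world and species pool

The generator exists because the pipeline's real inputs (occurrence
databases, trait compendia, Red List exports, protected-area polygons,
published phylogenies) cannot be redistributed. It emulates the statistical
structure the pipeline assumes, not the geography of any real ocean.

* **Grid.** A rectangular equal-area grid in projected km coordinates
  (default 10 km cells), row-major 0-based indexing, cells identified by
  their centers. Cell area is exactly `cell_km²`, so range size in km² is
  always `n_cells · cell_km²`.
* **Bathymetry.** A uniform random field box-smoothed four times and
  rescaled to `depth_range_m` (default 5–4,000 m) — spatially
  autocorrelated, nothing more.
* **Protection.** Independent Bernoulli(`pa_fraction`) per cell (default
  0.08, in the vicinity of current global marine-protection levels). No
  attempt at realistic protected-area geometry.
* **Taxonomy and traits.** Species are assigned to `n_families` families,
  each holding 2–5 genus slots. Continuous traits are drawn around
  family-level means (log-normal for growth *K* and maximum length; normal
  for trophic level) with within-family standard deviations deliberately
  below the between-family spread; each categorical trait has a
  family-preferred level inherited with probability 0.75. Species depth
  windows are drawn in quantile space of the world's bathymetry
  (family-clustered), so a species' known depth range always overlaps a
  sensible share of the seascape and depth refinement trims ranges rather
  than annihilating them.
* **Occurrences.** Per species, a bivariate normal cloud around a uniform
  center; the kernel width (log-uniform between 2% and 25% of the short
  grid side) controls range size; counts default to 6–40 points, clipped to
  the grid.
* **Latent threat process.** `logit P(Threatened) = intercept +
  β_range·z(log hull area) + β_size·z(log max length) + β_growth·z(K)`,
  with z-scores taken across the pool. Defaults `(-2.5, -1.5, +1.0, -1.0)`
  give a strongly imbalanced pool (roughly one Threatened species in ten)
  in which small-ranged, large, slow-growing species carry most of the
  risk — the attribute pattern the classifier is supposed to discover. The
  default signal is intentionally noisy; property tests that require label
  recovery construct pools with a stronger, documented signal
  (`beta_range ≤ −2`, intercept −1).
* **Status masking and missingness.** `ddne_fraction` (default 0.38, the
  DDNE share among marine teleosts) of species have their true status
  masked to DDNE. Per-trait missingness is missing-completely-at-random
  (default 10%); a `family_missingness` option blanks whole families
  instead, because real trait gaps are taxonomically clustered.
* **Seeding.** One master seed per stage group, split with
  `numpy.random.SeedSequence.spawn` in fixed order (world: depth,
  protection; pool: families, traits, occurrences, threat, status masking,
  missingness), so stages are individually reproducible.

What passing tests on this generator do **not** show: robustness to real
occurrence biases (uneven survey effort, coastline artifacts), realistic
trait covariance, or the true noise level of Red List labels. The generator
has a simple effort-free sampling scheme and no real coastline geometry.

## Range construction

Hulls are built per world quadrant (two split lines; default the grid
center, the synthetic analogue of the equator plus an ocean-dividing
meridian; points on a split line belong to the east/north quadrant).
Quadrants with 1–2 points or collinear points get a minimal polygon by
buffering the points with half a cell radius and clipping back into the
quadrant — species with few occurrences are kept, not dropped. Rasterization
uses boundary-inclusive cell-center membership, chosen for determinism and
oracle simplicity; an exhaustive center-in-polygon oracle checks it
cell-for-cell on small grids. The cells containing the occurrence points
themselves are always added before depth refinement, because a hull vertex
can sit so close to a cell corner that the cell center falls outside the
hull while the observation plainly belongs to the range. A cell's "maximal
depth" is the single depth-raster value for that cell; depth refinement
removes cells outside `[depth_min_m, depth_max_m]` and never adds cells.
The synthetic grid is equal-area by construction, so the real-data two-step
(coarse aggregation, then equal-area reprojection) collapses to direct
rasterization on the target grid. No minimum-range floor is enforced.

## Trait imputation

Per-trait holdout evaluation: complete cases are split 80/20; a random
forest (100 trees) predicting the trait from the other predictors is scored
on the held-out 20% (R² for continuous, accuracy for categorical). The gate
is **strictly** greater than 0.6 — ties at 0.6 fail. Species with more than
6 of the 12 predictors missing are excluded first and flagged
"unpredictable" (the cap is configurable; exclusion before imputation is a
documented ordering choice). The fill loop mirrors the iterative
forest-imputation recipe: initialize gated gaps at the column mean/mode,
then re-predict each incomplete gated trait (least-missing first) until the
imputed values change by less than 1e-3 (normalized squared change for
continuous, flip fraction for categorical) or 10 sweeps. Observed values
are never altered; ungated traits keep their gaps (they are patched with
neutral fills only inside the design matrix during the loop). No multiple
imputation: a single completed table is produced.

## Ensemble classification

Defaults: B = 24 balanced subsets, k = 10 stratified folds, consensus
threshold τ = 0.8. Non-Threatened samples are drawn from successive
shuffled permutations, so coverage is maximized: with `n_NT = B·n_T` the
samples form an exact partition. Learners: random forest (500 trees,
default split rule — class balance is guaranteed by the subsetting, so no
class weights) and a one-hidden-layer network (32 rectified units, patient
early stopping: 20% validation split, 40-round patience, initial learning
rate 0.01, ≤1,000 epochs — sized for the few-hundred-row balanced subsets
this pipeline produces). Continuous features are z-scored (range size on a
log₁₀ scale first) and categorical features — including genus and family,
which enter as ordinary categorical predictors — are one-hot encoded with
levels frozen on the full pool. Range size (km², from the range builder) is
a first-class predictor.

All B·k fold models vote on every DDNE species (a `refit_votes` flag
switches to B full-subset refits voting instead, since the reference
description is silent on which set votes). A call requires a strictly
greater than τ vote fraction for one class; exactly τ is NoCall. Species
with missing features after gating are NoCall with reason
`missing-features`; labeled rows with unresolved gaps are likewise left out
of training. Cross-validated metrics aggregate over all held-out folds:
accuracy, plus a three-way percentage tally (correct / NT-predicted-T /
T-predicted-NT) that partitions every evaluated case.

## Merging and transitions

The complementary rule is symmetric; both-NoCall maps to DDNE (the only
reading consistent with "no status when no algorithm can call"). The strict
variant's non-DDNE assignments are provably a subset of the complementary
ones. Previously assessed species never change category. Transition
summaries compute `100·(after−before)/before` per category and
`100·count/total` shares at full precision, rounding to one decimal only
for reporting.

## Explainability and phylogenetic signal

Importance: per-model `feature_importances_` averaged, one-hot columns
folded back into their source predictor, normalized to sum to 100%.
Partial dependence: the standard data-distribution average, swept over an
even grid and averaged over models.

The D statistic for a binary trait on a rooted tree: `Σd` is the sum over
internal nodes of the absolute differences between each child's value and
the node mean, with node values computed by recursive child averaging (for
bifurcating nodes this is exactly the absolute sister-clade difference).
`D = (Σd_obs − mean Σd_Brownian) / (mean Σd_random − mean Σd_Brownian)`.
The random null permutes tip labels; the Brownian null simulates Brownian
motion along branches (missing/zero branch lengths treated as 1) and
thresholds the tip values at the observed prevalence (top-k tips become
state 1 — the standard prevalence-matching choice for this estimator). Both
nulls default to 1,000 draws. D is undefined for constant traits (an error),
and `Σd` is exactly invariant to complementing the labels, so D is
label-coding invariant up to Monte-Carlo noise. With several candidate
trees, D is reported per tree and as mean ± SD.

## Gap analysis

The target rule is the two-anchor line in `(log₁₀ range, target%)` space:
100% at 10,000 km², 10% at 390,000 km², clamped outside the anchors. Any
log base gives the same line through two fixed points; base 10 is used for
reproducibility. Achievement = `100·coverage/target`, capped at 100% (the
cap is a deliberate choice — over-achievers are not more achieved than
"met" — with the uncapped value retained for audit). Protected-area inputs
tagged with IUCN management categories can be pre-filtered to classes
Ia–IV. Group comparisons use Kruskal–Wallis (≥3 groups) and two-sided
Mann–Whitney rank-sum tests from `scipy.stats`.

## Prioritization

Cell value defaults to the **additive** rule `Σⱼ wⱼ·qᵢⱼ` because that is
the rule the workflow being re-implemented verbally describes, even though
it names the core-area (max-benefit) variant; both are implemented and the
`value_mode` switch selects `max_benefit = maxⱼ wⱼ·qᵢⱼ`. `qᵢⱼ` is cell
*i*'s fraction of species *j*'s **remaining unprotected** distribution,
recomputed after every iteration (a flag re-includes protected cells in the
denominators; they are never removed, so they simply keep shrinking the
fractions). Warp removes the current `warp` lowest-valued cells in one
block without intra-block recomputation; within a block, and for ties
generally, the lowest linear cell index is removed first — deterministic
and matchable by the exhaustive oracle. Normalized rank is
`(removal position − 1)/(n_unprotected − 1)` (a single unprotected cell
gets rank 1.0). Weight-scale invariance holds by construction: multiplying
all weights by a constant rescales every cell value equally.

Sensitivity weights: evaluated species keep the fixed weights (1/2/6);
predicted species are weighted by the average vote fraction *p*. The
published phrasing "2 + p (rescaled between 2 and 5)" is ambiguous, so both
readings are implemented behind `WeightScheme.rescale`: the default
`affine-p` maps the admissible vote fractions (p ∈ (0.8, 1] for Threatened,
agreement 1−p ∈ (0.8, 1] for Non-Threatened) affinely onto [2, 5] and
[2, 1]; `rescale-sum` rescales the raw 2±p values onto the same intervals.
Both hit the stated endpoints.

## Problem sizes

The test-suite and acceptance runs use scaled-down study sizes chosen to
keep the statistical properties testable on a desktop: pools of 400–2,500
species on 30–100-cell-wide grids, 6 subsets × 3 folds ensembles with
150-tree forests, 50 replicate 64-tip trees with 200 null draws for the D
statistic, and greedy-ranking oracle checks on ≤ 4×4 grids. The reference
configuration (24 × 10 = 240 models of 500 trees, warp 1,000) remains the
package default.

## Known limitations

* The generator's missingness is MCAR by default; real trait gaps are
  informative.
* The network learner is a fixed small architecture, not tuned per data
  set; no probability calibration or hyperparameter search anywhere.
* Coverage is purely geometric — protected-area effectiveness is out of
  scope, as are connectivity penalties, cost layers and range dynamics.
* Per-subcategory (VU/EN/CR) prediction is not attempted; the three-way
  collapse is baked into the label set.
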