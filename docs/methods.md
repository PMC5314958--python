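# Methods

This note records the models, conventions, and design choices behind
`protgrad`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Unit of analysis

All statistics operate on a table of 0.5°×0.5° grid cells. A cell carries
its spherical-band area `R²·Δλ·(sin φ_top − sin φ_bot)` with R = 6371.0 km
(no ellipsoid; the error is < 0.5% and irrelevant to rank- and
share-based statistics), a terrestrial fraction, a protected fraction *of
its terrestrial area*, a region label, and 15 environmental covariates.
Cells with < 5% terrestrial fraction are excluded before any analysis.
Protection is a continuous per-cell fraction; polygon geometry of individual
protected areas is out of scope.

## Gradient histograms

* Class width for variable *i* defaults to (P97.5 − P2.5)/20 of the global
  distribution; the same width and boundaries are reused for every region so
  class-level measures are comparable across strata. The globe is an extra
  stratum computed from the union of cells, not a sum of regional
  histograms.
* Tail handling: cells below P2.5 / above the last interior boundary are
  pooled into single end classes bounded by the data extrema. Pooling moves
  class membership only; the totals Σ AREA and Σ AREA.PROT are conserved
  under any width and truncation (a tested invariant).
* Intervals are half-open [lower, upper); a value landing exactly on an
  interior boundary opens the upper class; the final class is closed.
* `FRAC.PROT` of a class is AREA.PROT / AREA, i.e. the terrestrial-area-
  weighted mean of cell protected fractions. Empty classes are retained
  structurally (AREA = 0, FRAC.PROT undefined) but excluded from evenness
  and regression inputs.
* Any histogram entering a statistical analysis must have ≥ 8 nonempty
  classes; otherwise the class width is halved (down to 2⁻¹⁰ of the initial
  width) until the rule is met, and an error is raised when the variable has
  too few distinct values to ever comply.

## Modified Shannon evenness

With x the per-class values of one measure, V = x/Σx, H = Σ V·ln V and
H′ = H / (n · min V·ln V), where n counts the nonempty classes used.
Conventions, all required for the index to be finite and bounded:

* 0·ln 0 := 0; zero-share classes contribute nothing to H and are excluded
  from the min term (otherwise any unprotected class would zero the
  denominator).
* If a single class holds all mass, H′ := 0 (the continuity limit).
* H is implemented exactly as the sum Σ V ln V (≤ 0, no minus sign); the
  normalizing ratio cancels the sign, so H′ ∈ [0, 1] with 1 for a constant
  profile.
* The normalization inherits a quirk: any vector whose nonzero shares all
  share the same value of V·ln V scores exactly 1 (e.g. (0.5, 0.25, 0.25)),
  because V ln V is not injective on (0, 1). This is asserted as a
  regression test, not hidden.
* Numerics: the index is exact in real arithmetic under rescaling and
  permutation, but ill-conditioned when one share exceeds the others by
  ~1/machine-eps; property tests bound the dynamic range accordingly.

H′ of FRAC.PROT diagnoses fraction representativeness; H′ of AREA.PROT
diagnoses quota representativeness; their ratio (> 1 ⇒ closer to fraction
representativeness) is reported per histogram, and is undefined (reported
missing) when the quota index is 0.

## Regression families

FRAC.PROT is regressed on class midpoints (tail classes use the midpoint of
their pooled bounds — the abscissa convention is ours). Families and
parameter counts: poly1 (2), poly2 (3), exponential a·e^{bx} (2), one-phase
y0+(plateau−y0)(1−e^{−kx}) with k > 0 (3), semilog a+b·ln x (2, skipped
when any x ≤ 0), continuous two-segment piecewise with breakpoint ψ (4).

* Exponential and one-phase are linear in their amplitude parameters
  conditional on the rate, so they are fitted by profiled least squares: a
  1-D search over the rate (u = ln k keeps k > 0) with ≥ 5 seeded Brent
  starts, solving the amplitudes by `lstsq` at each step. This is exact for
  these families and immune to the divergence of naive multi-dimensional
  starts.
* The piecewise breakpoint is grid-searched over interior midpoints of the
  sorted abscissa (≥ 2 points per segment) and refined by bounded scalar
  minimization; a test checks agreement with exhaustive search on a
  10⁻³-spaced grid.
* Selection uses Gaussian AIC = n·ln(RSS/n) + 2(k+1) (the +1 counts the
  error variance), identical across families; AICc is deliberately not the
  default. RSS below float-noise scale is snapped to 0 and scored as a −∞
  AIC sentinel, so exact fits from nested families tie and the tie rules
  (fewer parameters, then fixed family order) resolve them.
* Classes enter unweighted; pseudo-R² is the squared Pearson correlation of
  observed and predicted values. Regression targets FRAC.PROT; AREA.PROT can
  be analyzed through the same functions by passing its vector.
* A modeling floor of 8 points is enforced (the ≥ 8-class rule upstream).

**Known limitation — family identifiability.** In the recovery study
(20 classes on [0, 10], noise sd = 10% of the curve's range, 200 replicates
per family), the piecewise family's continuously optimized breakpoint
behaves as ~2–3 effective degrees of freedom while AIC charges it a flat 4
parameters, so it systematically captures replicates generated from smooth
families; sharpening the smooth curves only improves the two-segment
approximation. Re-selection rates are therefore high for poly2 and
piecewise (whose breakpoint is recovered well within one class width) but
sit below the nominal target for the smooth families — an intrinsic
property of plain-AIC selection over this family set at these sizes, not of
the fitters (each family attains RSS ≈ 0 on its own noiseless curve). The
study's generating curves are realistic protected-fraction profiles fixed
once: poly1 (0.05, 0.02), poly2 (0.02, 0.06, −0.005), exponential
(0.015, 0.28), one-phase (0, 0.3, 0.5), semilog (0.15, 0.07), piecewise
(ψ = 5, slopes 0 and 0.04).

## Random forest importance

* Response: per-cell protected fraction; predictors: the nine preferential +
  opportunistic variables. Biophysical variables are excluded — their
  importance would measure the failure of representativeness, not a driver.
  Cells (not histogram classes) are the observations: a multivariate forest
  needs joint covariate observations, which single-variable class records
  cannot supply.
* The forest is a bagged ensemble of fully grown scikit-learn regression
  trees (bootstrap resampling at the ensemble level, per-split `max_features
  = mtry` at the tree level) — mathematically a regression random forest,
  built this way because the ensemble API exposes the per-tree bootstrap
  samples that OOB statistics require. Defaults: ntree = 500, nodesize = 1.
* `mtry` is tuned by fitting one forest per candidate (all integers 1..p) at
  a fixed seed and minimizing OOB-MSE; ties go to the smaller candidate.
  Tuning requires ≥ 50 cells (the OOB estimate is too unstable below that).
* Importance: per tree, the OOB MSE is recorded before and after permuting
  each predictor's OOB values; the per-tree differences are averaged and
  divided by their standard deviation (ddof = 1; if the sd is 0 the mean is
  used unnormalized). Negative raw importances are clipped to 0 and the
  vector is scaled to percentages summing to 100; raw values are preserved
  for audit. Group averages pre-average animal and plant richness before
  the preferential-group mean.
* Collinearity among predictors is documented with a Kendall τ-b matrix
  (constant variables reported as missing); the forest mitigates but does
  not remove collinearity effects.

## Synthetic worlds

The generator emulates the study grid so that parameter recovery is
measurable; defaults are the standard conditions used by the test suite.

* Grid: 0.5° resolution over configurable lat/lon ranges (default
  50°×25° ⇒ 5,000 cells), seven contiguous longitudinal regions.
* Land/ocean: terrestrial fraction = clipped smooth periodic field (mean
  0.8, amplitude 0.25, periods 70°/55°) plus N(0, 0.1) noise — mostly
  terrestrial so the 5% filter bites only slivers.
* Covariates: a joint latent Gaussian field with a user-requested
  correlation structure (validated positive semi-definite, rejected
  otherwise) plus smooth cos(latitude) gradients, pushed through monotone
  marginal transforms (log-normal population, bounded 0–100 cropland
  suitability, shifted-logistic richness, ...). Monotonicity preserves the
  sign of requested correlations on the rank (Kendall) scale; the default
  correlation map includes the positive richness–cropland-suitability
  association observed in real data.
* Regimes: `fraction` protects every cell at the target rate (with mild
  relative jitter); `quota` gives every standard analysis class of the
  driver gradient an equal absolute protected area, spread uniformly over
  the class's terrestrial area and capped at the class area (with a logged
  warning) when a class is too small; `preferential`/`opportunistic` set the
  cell protected fraction by a logistic link over signed effect sizes on the
  standardized latent drivers plus noise, with the intercept solved by
  bisection so the area-weighted protected share hits the target; `mixed`
  blends regime components with convex weights so recovery tests can plant
  a dominance order.
* What the generator does *not* emulate: polygon geometry, spatial
  autocorrelation beyond the latitudinal gradients and the smooth land
  field, historical dynamics of protection, and measurement error in the
  covariates. Passing recovery tests therefore show that the statistics
  recover planted structure of this kind, not that real-world protection
  obeys it.

## Problem sizes and determinism

Recovery studies are sized to run on one CPU: evenness-regime checks use
5,000-cell worlds (10 seeds per regime); the forest recovery study uses
625-cell worlds for 20 replicates of full OOB tuning (9 candidate forests ×
500 trees each) plus the final forest — recovery at that size is unambiguous
(the planted driver takes ~55% of the importance). Every stochastic step is
seeded (NumPy `default_rng`, scikit-learn `random_state`); a pipeline rerun
with the same config and seed reproduces byte-identical CSV outputs, and the
run manifest records seed, versions, and counts.
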