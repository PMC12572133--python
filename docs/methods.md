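# Methods

`confaudit` audits a common failure mode of predictive modeling with
nuisance covariates: *confound leakage*, in which regressing confounds out
of the features — the standard residualization step — paradoxically
*injects* confound information into them in a form that nonlinear
predictors exploit, inflating cross-validated performance. The package
implements the full audit pipeline (cross-validated prediction with
in-fold confound removal, Gini-importance reporting, a feature-permutation
null, and a condition grid), plus a synthetic generator that reproduces
the regime in which the leakage occurs, so every stage can be tested
without access to human data.

## The pipeline

For a feature matrix `X` (n × p), confound matrix `C` (n × q) and a
continuous target `y`, one audit run is a k-fold cross-validation
(default k = 10). Within each fold, using training rows only:

1. **z-scoring** — each feature is centered and scaled to unit variance
   with training-fold statistics; held-out rows are transformed with the
   same statistics. Zero-variance training features get scale 1 with a
   warning.
2. **confound removal** — each feature is regressed on the confounds and
   replaced by its residual, `X_j − f̂_j(C)`. The removal family is
   pluggable: ordinary least squares (default), ridge, random forest,
   extremely randomized trees, or `none` (confounds unused anywhere —
   not appended as features, which would be a different experiment).
   The remover is fitted on training rows only and applied to both sides;
   fitting and application are separate pure operations, so in-fold
   discipline holds by construction.
3. **prediction** — a `RandomForestRegressor` (default 100 trees, all
   features eligible per split, fixed seed) is fitted on the processed
   training rows and scored on the held-out rows with the coefficient of
   determination R² = 1 − SS_res/SS_tot. R² is reported as computed: a
   negative value means the training-fold mean would have predicted the
   held-out rows better than the model.

The reported score is the mean over the k fold scores. Gini importances
(impurity-based, normalized to sum to 1) are collected per fold and
aggregated as elementwise mean ± SD with a deterministic ranking
(descending mean, lexicographic tie-break).

**Fold construction.** Continuous targets are stratified by quantile
binning: `y` is cut into `n_bins` quantile bins (default 10; boundary
ties go to the lower bin), members of each bin are shuffled with the
seeded generator and dealt round-robin across folds. Fold sizes differ by
at most one and every fold approximately follows the target's marginal
distribution. Degenerate targets fall back with a warning: fewer distinct
values than bins → rank-based binning; constant target → plain seeded
k-fold.

**Stage order.** Scaling precedes residualization so removal-model
hyperparameters (the ridge penalty in particular) are scale-free. For
this pipeline the choice is provably inert downstream: z-scoring is a
per-feature affine map, linear/ridge/forest removers all commute with
affine maps of their targets, and tree splits are invariant under
per-feature monotone transforms — so fold-wise and global scaling give
identical forest predictions. The `global_scaling` sensitivity flag
exists to demonstrate exactly this invariance (a test asserts it), which
also means the scaling stage cannot itself be a leakage vector for tree
predictors.

## The feature-permutation test

To ask whether predictive information stems from the features rather than
from the confounds alone, each feature column is permuted *independently*
(destroying the feature–target association while the confound–target
association is untouched), and the full CV pipeline is rerun per
permutation. The fold assignments depend only on the unpermuted `y`, so
they are identical across permutations; the permutation RNG is a separate
stream from the pipeline seed, so changing the number of permutations
never changes the observed score.

The p-value is the exceedance proportion `#{null ≥ observed} / N`
(smoothing off, the default). With this plain estimator, rejecting at
`p ≤ α` has exact level `⌊α(N+1)⌋/(N+1)` under exchangeability — the
package's simulation studies use N = 39, for which the level at α = 0.05
is exactly 2/40 = 0.05. The optional smoothed estimate
`(1 + #{null ≥ obs}) / (1 + N)` is available because a reported p of
exactly 0 is statistically improper. The test is directional (an upper
tail on R²) even where significance conventions are described as
two-tailed α = 0.05 elsewhere; we implement the exceedance formula and
treat α purely as the labeling threshold. Permuting `y` instead is
deliberately unsupported: it would break the confound–target association
the test is designed to preserve.

## The condition grid and the leakage diagnostic

`run_condition_grid` runs one CV (optionally plus a permutation test) per
(removal family × stratification) condition — the default grid is 5
families × 2 = 10 rows per target — all sharing one base seed so rows
differ only in the condition. The leakage diagnostic is
`Δ = R²(with removal) − R²(without removal)`: on data whose features
carry no target signal beyond the confounds, any positive Δ means the
removal procedure added exploitable information. Raw p-values are
reported unadjusted across the grid (an optional Benjamini–Hochberg
correction was considered and left out of the default to keep the table
a faithful per-condition report). `batch_targets` summarizes many targets
at once, flagging mean R² > 0 and > 0.1 (the conventional threshold for a
reasonable fit in this setting).

## The synthetic generator

The generator emulates the tabular shape of a speech-biomarker study of
cognitive performance — n ≈ 230 participants, a couple hundred acoustic
features, three demographic confounds (continuous age-like, binary
sex-like, 4-level ordinal education-like) — without emulating any
acoustic semantics. Construction, all from one master seed:

* standardized confounds `C̃`; target `y = ρ·C̃₁ + √(1−ρ²)·η` so that
  corr(C₁, y) → ρ;
* features `X_j = a·(w_j·C̃) + b·y + σ·ε` with unit-norm random mixing
  weights `w_j`, confound loading `a`, target loading `b` (b = 0 is the
  pure-leakage regime) and noise σ, all on the latent scale;
* a marginal transform (identity / exponentiation / integer rounding)
  and finally round-half-even precision rounding — applied last, so the
  loadings are defined pre-transform (post-transform correlations are
  attenuated accordingly).

**Leakage preset** (`leakage_scenario`): n = 230, p = 100, q = 3,
ρ = 0.65, confound loading 0.5, target loading 0, noise 2.0, lognormal
marginals rounded to integers. The combination of skew and coarse
rounding makes each raw feature an unbalanced, few-valued column whose
*individual* confound information is weak, while its OLS residual embeds
the continuous fitted confound combination `−β̂ᵀC` exactly — within any
feature level the residual orders samples by the confound prediction, and
a forest inverts that ordering. This is the mechanism by which removal
*raises* CV R² on confound-only data; with this preset the with-removal
score exceeds the without-removal score in 10/10 seeds (mean Δ ≈ +0.24).
The moderate loading is essential: with strongly confound-loaded features
the raw features already carry the confound signal cleanly and removal
(correctly) hurts.

**Pure-noise preset** (`pure_noise_scenario`): n = 200, p = 20, features
independent of confounds and target (both loadings 0), while the
confound–target correlation stays 0.3 — the global null used to check
test calibration, with the confound channel intact.

**Signal preset** (`signal_scenario`): the pure-noise preset with target
loading 0.23, calibrated once by simulation so a 25-tree forest reaches
out-of-sample R² ≈ 0.3 at this shape; used to exercise test power.

What the generator does **not** emulate: real acoustic feature
covariance (features are conditionally independent given confounds and
target), nonlinear confound effects, heteroscedasticity, missing data,
or measurement error in the confounds. Passing tests therefore show that
the pipeline detects/avoids leakage under the stated generative regime,
not that any particular real dataset is leakage-free.

## Numerical and design choices

* All randomness flows from integer seeds through `numpy`'s Generator;
  identical config + seed is bit-identical output end to end, including
  forest removers/predictors (seeded sklearn estimators, `n_jobs=1`).
* Rounding is round-half-even (numpy default) for cross-platform
  reproducibility; quantile-boundary ties go to the lower bin.
* Linear-family removal is a single vectorized multi-target OLS
  (`lstsq` on `[1 | C]`), mathematically identical to one independent
  regressor per feature; a rank-deficient confound matrix raises an
  error naming the dependent columns (pivoted QR). Ridge standardizes
  the confounds with training statistics so its default penalty
  (α = 1.0) is comparable across confound scales; an intercept is always
  included, so linear/ridge training residuals are centered to ~1e-15.
* Forest-family removers fit one seeded forest per feature (default 100
  trees) — expensive but faithful to per-feature residualization.
* A forest in which no tree ever split (constant target) reports the
  uniform importance vector 1/p with a warning, keeping the sum-to-one
  contract for every fitted forest.
* Errors carry context: configuration errors name the offending field,
  CV failures carry the fold index, grid/batch failures are tagged in
  their row rather than aborting the run.

## Problem sizes of the simulation studies

The package's own studies (acceptance tests and `scripts/acceptance.py`)
run on one CPU, and sizes were chosen for that budget: the calibration
and power studies use 30 datasets × 39 permutations (script: 20 datasets)
with 5-fold CV and 25-tree forests at n = 200, p = 20; the leakage
signature uses 10 seeds of the full n = 230, p = 100 preset with 10-fold
CV and 100-tree forests; the stratification study uses 50 seeds. The
calibration argument above is exact at any N, so a larger N buys p-value
resolution, not validity; rate estimates over 20–30 datasets carry
binomial error that the tests account for explicitly (the 99% band for a
5% rate over 30 datasets is 0–5 rejections).

## Known limitations

* Only continuous targets and R² scoring; no classification mode.
* No nested CV or hyperparameter search: the audit compares fixed
  pipelines, it does not tune them.
* The leakage diagnostic Δ is a flag, not a measure of confound
  contribution; attribution beyond "features vs. confounds alone" needs
  the permutation test, and a non-significant result does not localize
  which confound leaked.
* Categorical confounds must arrive as numeric codes; the package does
  not encode or select confounds.
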