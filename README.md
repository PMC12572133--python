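# confaudit

**Audit toolkit for confound leakage in cross-validated prediction of
continuous targets.**

Regressing confounds (age, sex, education, scanner site, ...) out of the
features before fitting a predictive model is standard practice across
biostatistics, epidemiology and neuroscience. It is also quietly
dangerous: with nonlinear predictors, the residualization step can
*inject* confound information into the features instead of removing it —
confound leakage — inflating cross-validated performance on data whose
features carry no genuine signal. The symptom is paradoxical: the model
scores *better* with confound removal than without, exactly when the
confounds correlate strongly with the target and the features are
numerous, skewed, or of limited precision.

`confaudit` packages the audit that exposes this:

* **Cross-validated prediction** of a continuous target `y` from features
  `X` with in-fold preprocessing: per-fold z-scoring, per-fold confound
  removal (each feature replaced by its residual `X_j − f̂_j(C)`, remover
  fitted on training rows only), a seeded random-forest regressor, and
  R² = 1 − SS_res/SS_tot scoring (negative values reported as such).
  Removal families: OLS, ridge, random forest, extra-trees, or none.
* **Target-stratified k-fold CV** for regression via quantile binning, as
  an sklearn-style splitter (`StratifiedRegressionKFold`).
* **Gini importances** per fold, aggregated as mean ± SD with a
  deterministic ranking.
* **A feature-permutation test**: each feature column permuted
  independently — the feature–target association is destroyed while the
  confound–target association is preserved — with the empirical null of
  mean CV R² and the exceedance p-value `#{null ≥ observed}/N`.
* **A condition grid** (removal families × stratification) and the
  leakage diagnostic `Δ = R²(with removal) − R²(without removal)`;
  `Δ > 0` on confound-only data flags leakage.
* **A synthetic generator** of confounded tabular data with controllable
  confound–target correlation, loadings, skew and precision — including a
  preset (`leakage_scenario`) that reproduces the leakage regime, so the
  entire audit is testable end to end without human data.

## Worked example

Generate a confound-only dataset (n = 230, 100 skewed limited-precision
features, corr(confound, target) ≈ 0.65, features carrying *no* target
signal beyond the confounds), then contrast linear confound removal with
no removal:

```bash
confaudit simulate --preset leakage --seed 1 --out-dir example
confaudit grid \
  --features example/features.csv --confounds example/confounds.csv \
  --targets example/targets.csv --seed 1 \
  --families linear,none --strat true --out example/results
```

which prints (about half a minute):

```
target removal_family  stratified  mean_r2  p_value  n_folds  seed error
target         linear        True 0.275078      NaN       10     1
target           none        True 0.062190      NaN       10     1
```

Reading: these features predict nothing — the target depends only on the
confounds. Yet the pipeline *with* confound removal reports mean CV
R² ≈ 0.275 while the honest no-removal pipeline reports ≈ 0.062: removal
added ~0.21 of spurious R² (the leakage delta). On real data this
signature — removal raising performance — is the cue to distrust the
headline score and run the permutation test (199 rebuilds of the 10-fold
pipeline, ~15 min on one CPU; lower `--n-perm` for a quick look):

```bash
confaudit permtest \
  --features example/features.csv --confounds example/confounds.csv \
  --targets example/targets.csv --seed 1 --n-perm 199 --out example/perm
```

```
{"observed_score": 0.2750781149002721, "p_value": 0.964824120603015,
 "null_min": 0.250984379590831, "null_median": 0.3103846957419555,
 "null_max": 0.36520035454334254, "n_permutations": 199}
```

The observed R² sits deep inside the permutation null (p ≈ 0.96): the
"performance" fully survives the destruction of every feature–target
association, so it stems from the confounds alone. Note the null itself
is centered near R² ≈ 0.31 — even *permuted* features reach that score,
because the in-fold removal step injects the fitted confound combination
into every residualized feature. That is confound leakage in its purest
form, and it is why a permutation null that preserves the
confound–target association (rather than a naive "noise should score
zero" intuition) is the right reference distribution.

The same machinery is available as a library:

```python
from confaudit import (PipelineConfig, RemovalModelSpec, leakage_scenario,
                       run_cv, leakage_delta)

ds = leakage_scenario(seed=1)
base = dict(k_folds=10, stratify=True, seed=1)
with_cr = run_cv(ds.X, ds.C, ds.y, PipelineConfig(removal=RemovalModelSpec("linear"), **base))
without = run_cv(ds.X, ds.C, ds.y, PipelineConfig(removal=RemovalModelSpec("none"), **base))
print(leakage_delta(with_cr.mean_score, without.mean_score))
```

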