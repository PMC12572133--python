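"""Cross-validated prediction with in-fold preprocessing.

The pipeline per fold: z-score features with training-fold statistics,
residualize them against the confounds with a remover fitted on the
training fold only, fit a random-forest regressor, and score the held-out
fold with the coefficient of determination.  Fold construction for
continuous targets is quantile-stratified so every fold approximately
follows the target's marginal distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from ._exceptions import ConfigurationError, DataError, FoldError, UndefinedScoreError
from .importance import importance_from_forest
from .removal import RemovalModelSpec, fit_remover

__all__ = [
    "PipelineConfig",
    "CVResult",
    "StratifiedRegressionKFold",
    "stratified_folds",
    "r_squared",
    "run_cv",
    "fit_final_estimator",
]

#: Predictor defaults: a conventional forest with every feature eligible
#: at each split and a fixed seed for determinism.
DEFAULT_PREDICTOR: dict[str, Any] = {"n_estimators": 100, "max_features": 1.0}


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one cross-validated prediction run."""

    k_folds: int = 10
    stratify: bool = True
    n_strat_bins: int = 10
    removal: RemovalModelSpec = field(default_factory=RemovalModelSpec)
    predictor: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    global_scaling: bool = False  # sensitivity flag; fold-wise scaling is the default
    compute_importances: bool = True

    def __post_init__(self):
        if self.k_folds < 2:
            raise ConfigurationError(f"k_folds must be >= 2, got {self.k_folds}")
        if self.n_strat_bins < 2:
            raise ConfigurationError(f"n_strat_bins must be >= 2, got {self.n_strat_bins}")

    def predictor_params(self) -> dict[str, Any]:
        return {**DEFAULT_PREDICTOR, **self.predictor}


@dataclass(frozen=True)
class CVResult:
    """Per-fold scores and importances of one cross-validation run."""

    fold_scores: np.ndarray
    mean_score: float
    fold_importances: np.ndarray | None
    fold_assignments: np.ndarray

    @property
    def k(self) -> int:
        return len(self.fold_scores)


def stratified_folds(y, k: int, n_bins: int, seed: int) -> np.ndarray:
    """Quantile-stratified fold labels for a continuous target.

    y is cut into ``n_bins`` quantile bins (boundary ties go to the lower
    bin); within each bin members are shuffled with the seeded generator
    and dealt round-robin across the ``k`` folds, so fold sizes differ by
    at most one and every fold approximately follows the target's
    distribution.  Degenerate targets fall back with a warning: fewer
    distinct values than bins triggers rank-based binning, a constant
    target a plain seeded equal partition.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    if n < k:
        raise ConfigurationError(f"need at least k={k} samples, got {n}")
    if n_bins < 2:
        raise ConfigurationError(f"n_bins must be >= 2, got {n_bins}")
    rng = np.random.default_rng(seed)

    n_distinct = np.unique(y).size
    if n_distinct == 1:
        warnings.warn("constant target: falling back to a plain seeded k-fold partition")
        order = rng.permutation(n)
    elif n_distinct < n_bins:
        warnings.warn(
            f"target has {n_distinct} distinct values < n_bins={n_bins}: "
            "falling back to rank-based binning"
        )
        order = _bin_order(np.argsort(y, kind="stable"), np.array_split(np.arange(n), n_bins), rng)
    else:
        edges = np.quantile(y, np.linspace(0, 1, n_bins + 1))[1:-1]
        # side="left": a value equal to an edge counts strictly-less edges
        # only, i.e. boundary ties land in the lower bin
        bins = np.searchsorted(edges, y, side="left")
        groups = [np.flatnonzero(bins == b) for b in range(n_bins)]
        order = _bin_order(np.arange(n), groups, rng, direct=True)

    labels = np.empty(n, dtype=int)
    labels[order] = np.arange(n) % k
    return labels

def _bin_order(base, groups, rng, direct=False):
    """Concatenate bins, shuffling members within each bin."""
    parts = []
    for g in groups:
        idx = g if direct else base[g]
        parts.append(rng.permutation(idx) if len(idx) else idx)
    return np.concatenate(parts) if parts else np.empty(0, dtype=int)


class StratifiedRegressionKFold:
    """sklearn-style CV splitter: target-stratified k-fold for regression.

    Stratification uses quantile binning of the continuous target (see
    :func:`stratified_folds`).
    """

    def __init__(self, n_splits: int = 10, n_bins: int = 10, seed: int = 0):
        self.n_splits = n_splits
        self.n_bins = n_bins
        self.seed = seed

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return self.n_splits

    def split(self, X, y, groups=None):
        labels = stratified_folds(y, self.n_splits, self.n_bins, self.seed)
        for f in range(self.n_splits):
            test = np.flatnonzero(labels == f)
            train = np.flatnonzero(labels != f)
            yield train, test


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot.

    May be negative out of sample: negative values mean the mean of the
    data alone fits better than the model's predictions.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise DataError(
            f"r_squared: length mismatch ({y_true.shape[0]} vs {y_pred.shape[0]})"
        )
    if y_true.size < 2:
        raise DataError("r_squared needs at least two observations")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedScoreError("R^2 is undefined for a constant y_true")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def _plain_folds(n: int, k: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    labels = np.empty(n, dtype=int)
    labels[rng.permutation(n)] = np.arange(n) % k
    return labels


def _scale_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("zero-variance training feature(s): scale set to 1")
        sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def fold_labels_for(y, config: PipelineConfig, n: int) -> np.ndarray:
    """Fold assignment used by run_cv for this target and config."""
    if config.stratify:
        return stratified_folds(y, config.k_folds, config.n_strat_bins, config.seed)
    return _plain_folds(n, config.k_folds, config.seed)


def run_cv(X, C, y, config: PipelineConfig, *, fold_assignments=None) -> CVResult:
    """Cross-validated forest prediction with in-fold confound removal.

    Per fold: fit the z-scorer on training rows, transform both sides;
    fit the confound remover on the scaled training rows (skipped for
    family "none") and apply it to both sides; fit the forest predictor
    with the configured seed; score held-out rows with :func:`r_squared`.

    ``fold_assignments`` overrides fold construction (used by the
    permutation test, whose folds are fixed across permutations).
    """
    X = np.asarray(X, dtype=float)
    C = np.asarray(C, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or C.ndim != 2:
        raise DataError("X and C must be 2-D matrices")
    n = X.shape[0]
    if C.shape[0] != n or y.shape[0] != n:
        raise DataError("X, C and y must share their row count")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(C)) and np.all(np.isfinite(y))):
        raise DataError("missing or non-finite values are not allowed")
    if config.k_folds > n:
        raise ConfigurationError(f"k_folds={config.k_folds} exceeds n_samples={n}")

    if fold_assignments is None:
        fold_assignments = fold_labels_for(y, config, n)
    else:
        fold_assignments = np.asarray(fold_assignments, dtype=int)

    predictor_params = config.predictor_params()
    k = config.k_folds
    fold_scores = np.empty(k)
    fold_importances = np.empty((k, X.shape[1])) if config.compute_importances else None

    if config.global_scaling:
        mu_g, sd_g = _scale_params(X)

    for f in range(k):
        test = fold_assignments == f
        train = ~test
        try:
            if config.global_scaling:
                mu, sd = mu_g, sd_g
            else:
                mu, sd = _scale_params(X[train])
            X_tr = (X[train] - mu) / sd
            X_te = (X[test] - mu) / sd

            if config.removal.family != "none":
                remover = fit_remover(X_tr, C[train], config.removal)
                X_tr = remover.transform(X_tr, C[train])
                X_te = remover.transform(X_te, C[test])

            forest = RandomForestRegressor(
                random_state=config.seed, n_jobs=1, **predictor_params
            )
            forest.fit(X_tr, y[train])
            fold_scores[f] = r_squared(y[test], forest.predict(X_te))
            if config.compute_importances:
                fold_importances[f] = importance_from_forest(forest)
        except Exception as exc:  # attach the fold index for diagnosis
            stage = "scale/remove/predict"
            raise FoldError(f, stage, exc) from exc

    return CVResult(
        fold_scores=fold_scores,
        mean_score=float(fold_scores.mean()),
        fold_importances=fold_importances,
        fold_assignments=fold_assignments,
    )


def fit_final_estimator(X, C, y, config: PipelineConfig):
    """Fit the scale -> residualize -> predict pipeline on the full data.

    Per-fold importances estimate the variability of the importance; the
    final estimator, refitted on all (processed) rows, provides the point
    estimate.  Returns the fitted forest and its Gini importance vector.
    """
    X = np.asarray(X, dtype=float)
    C = np.asarray(C, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    mu, sd = _scale_params(X)
    X_proc = (X - mu) / sd
    if config.removal.family != "none":
        remover = fit_remover(X_proc, C, config.removal)
        X_proc = remover.transform(X_proc, C)
    forest = RandomForestRegressor(
        random_state=config.seed, n_jobs=1, **config.predictor_params()
    )
    forest.fit(X_proc, y)
    return forest, importance_from_forest(forest)
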