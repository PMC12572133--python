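"""Confound removal by residualization with pluggable regression families.

Each feature column is regressed on the confounds with one of several
model families (ordinary least squares, ridge, random forest, extremely
randomized trees, or a pass-through "none" family) and replaced by its
residual.  Fitting and application are strictly separated so the remover
can be fitted on training rows only and applied to held-out rows — the
discipline required to keep cross-validation leak-free.

``ConfoundRemover`` follows the sklearn estimator protocol (get_params /
set_params, fitted attributes with trailing underscores) except that
``fit`` and ``transform`` take the confound matrix as a second positional
argument: confounds are row-aligned side information, not a prediction
target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
from sklearn.linear_model import Ridge

from ._exceptions import ConfigurationError, DataError, SingularConfoundsError

__all__ = ["RemovalModelSpec", "ConfoundRemover", "fit_remover", "apply_remover"]

REMOVAL_FAMILIES = ("linear", "ridge", "random_forest", "extra_trees", "none")
_FOREST_FAMILIES = {"random_forest": RandomForestRegressor, "extra_trees": ExtraTreesRegressor}


@dataclass(frozen=True)
class RemovalModelSpec:
    """Family plus hyperparameters of the confound-removal regressor.

    Forest families must carry a ``random_state`` hyperparameter so that
    removal is deterministic end-to-end; the pass-through family carries
    no hyperparameters at all.
    """

    family: str = "linear"
    hyperparameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in REMOVAL_FAMILIES:
            raise ConfigurationError(
                f"removal family must be one of {REMOVAL_FAMILIES}, got {self.family!r}"
            )
        if self.family == "none" and self.hyperparameters:
            raise ConfigurationError("family 'none' carries no hyperparameters")
        if self.family in _FOREST_FAMILIES and "random_state" not in self.hyperparameters:
            raise ConfigurationError(
                f"family {self.family!r} requires a 'random_state' hyperparameter "
                "for deterministic removal"
            )


def _check_pair(X, C, *, context: str) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    C = np.asarray(C, dtype=float)
    if X.ndim != 2 or C.ndim != 2:
        raise DataError(f"{context}: X and C must be 2-D matrices")
    if X.shape[0] != C.shape[0]:
        raise DataError(
            f"{context}: row counts differ (X has {X.shape[0]}, C has {C.shape[0]})"
        )
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(C)):
        raise DataError(f"{context}: missing or non-finite values are not allowed")
    return X, C


def _dependent_columns(D: np.ndarray) -> list[int]:
    """Indices of columns (of [1 | C], reported without the intercept) that
    are linearly dependent on earlier ones, via rank-revealing pivoted QR."""
    rank = np.linalg.matrix_rank(D)
    _, _, piv = scipy.linalg.qr(D, mode="economic", pivoting=True)
    # pivot order lists the most independent columns first; the tail is dependent
    dependent = sorted(piv[rank:])
    return [j - 1 for j in dependent if j >= 1] or [int(j) for j in dependent]


class ConfoundRemover(BaseEstimator):
    """Residualize features against confounds, one regressor per feature.

    Parameters
    ----------
    family:
        One of ``linear``, ``ridge``, ``random_forest``, ``extra_trees``,
        ``none``.
    hyperparameters:
        Family hyperparameters: ``alpha`` for ridge (default 1.0),
        sklearn forest keyword arguments (``n_estimators`` defaults to
        100; ``random_state`` is required) for the forest families.

    Attributes
    ----------
    n_features_in_ : int
        Number of feature columns seen during fit.
    n_confounds_in_ : int
        Number of confound columns seen during fit.
    feature_means_ : ndarray of shape (n_features,)
        Training-set feature means.
    coef_ : ndarray of shape (n_confounds + 1, n_features)
        OLS coefficients (intercept first), linear family only.
    models_ : list of fitted regressors
        Per-feature regressors, forest families only.
    """

    def __init__(self, family: str = "linear", hyperparameters: dict | None = None):
        self.family = family
        self.hyperparameters = hyperparameters

    def _spec(self) -> RemovalModelSpec:
        return RemovalModelSpec(self.family, dict(self.hyperparameters or {}))

    def fit(self, X, C):
        spec = self._spec()
        X, C = _check_pair(X, C, context="fit")
        n, p = X.shape
        q = C.shape[1]

        if spec.family == "linear" and n <= q + 1:
            raise DataError(
                f"linear removal needs n_train > n_confounds + 1 (got n={n}, q={q})"
            )

        self.n_features_in_ = p
        self.n_confounds_in_ = q
        self.feature_means_ = X.mean(axis=0)

        if spec.family == "none":
            pass
        elif spec.family == "linear":
            D = np.column_stack([np.ones(n), C])
            if np.linalg.matrix_rank(D) < q + 1:
                raise SingularConfoundsError(_dependent_columns(D))
            # multi-target OLS == independent per-feature regressions
            self.coef_, *_ = np.linalg.lstsq(D, X, rcond=None)
        elif spec.family == "ridge":
            params = dict(spec.hyperparameters)
            alpha = params.pop("alpha", 1.0)
            # standardize confounds with training statistics so alpha is
            # comparable across confound scales
            self.confound_mean_ = C.mean(axis=0)
            sd = C.std(axis=0)
            self.confound_scale_ = np.where(sd == 0, 1.0, sd)
            C_std = (C - self.confound_mean_) / self.confound_scale_
            self.ridge_ = Ridge(alpha=alpha, fit_intercept=True, **params)
            self.ridge_.fit(C_std, X)
        else:
            cls = _FOREST_FAMILIES[spec.family]
            params = {"n_estimators": 100, **spec.hyperparameters}
            self.models_ = []
            for j in range(p):
                model = cls(**params)
                model.fit(C, X[:, j])
                self.models_.append(model)
        return self

    def _predict_features(self, C: np.ndarray) -> np.ndarray:
        family = self.family
        if family == "linear":
            D = np.column_stack([np.ones(C.shape[0]), C])
            return D @ self.coef_
        if family == "ridge":
            C_std = (C - self.confound_mean_) / self.confound_scale_
            return self.ridge_.predict(C_std)
        return np.column_stack([m.predict(C) for m in self.models_])

    def transform(self, X, C) -> np.ndarray:
        """Residuals ``X - prediction(C)``; never re-fits."""
        if not hasattr(self, "n_features_in_"):
            raise DataError("ConfoundRemover.transform called before fit")
        X, C = _check_pair(X, C, context="transform")
        if X.shape[1] != self.n_features_in_:
            raise DataError(
                f"transform: expected {self.n_features_in_} feature columns, got {X.shape[1]}"
            )
        if C.shape[1] != self.n_confounds_in_:
            raise DataError(
                f"transform: expected {self.n_confounds_in_} confound columns, got {C.shape[1]}"
            )
        if self.family == "none":
            return X.copy()
        return X - self._predict_features(C)

    def fit_transform(self, X, C) -> np.ndarray:
        return self.fit(X, C).transform(X, C)


def fit_remover(X_train, C_train, spec: RemovalModelSpec) -> ConfoundRemover:
    """Fit one per-feature removal regressor of the requested family."""
    return ConfoundRemover(spec.family, dict(spec.hyperparameters)).fit(X_train, C_train)


def apply_remover(remover: ConfoundRemover, X, C) -> np.ndarray:
    """Apply a fitted remover to (possibly held-out) rows."""
    return remover.transform(X, C)
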