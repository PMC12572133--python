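"""Feature-permutation null for the cross-validated score.

Each feature column is permuted independently, destroying the
feature-target association while leaving the confound-target association
untouched (confounds and target are never permuted).  The cross-validated
score is rebuilt under every permutation with the same pipeline seed and
the same fold assignments (folds depend only on the unpermuted target),
and the observed score is located in the resulting empirical null.  A
significant p-value indicates that predictive information stems from the
features rather than from the confounds alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._exceptions import BudgetError, ConfigurationError
from .cv import PipelineConfig, fold_labels_for, run_cv

__all__ = ["PermutationConfig", "PermutationResult", "permute_features", "permutation_test"]


@dataclass(frozen=True)
class PermutationConfig:
    """Settings of the feature-permutation test.

    With ``smoothing`` off, p is the plain exceedance proportion
    ``#{null >= observed} / n_permutations``, which can be exactly zero;
    with smoothing on it is ``(1 + #{null >= observed}) /
    (1 + n_permutations)``, the add-one estimate that never reaches zero.
    """

    n_permutations: int = 1000
    seed: int = 0
    alpha: float = 0.05
    smoothing: bool = False
    max_model_fits: int | None = None

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ConfigurationError(
                f"n_permutations must be >= 1, got {self.n_permutations}"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha}")


@dataclass(frozen=True)
class PermutationResult:
    observed_score: float
    null_scores: np.ndarray
    p_value: float
    config: PermutationConfig = field(default_factory=PermutationConfig)


def permute_features(X, rng: np.random.Generator) -> np.ndarray:
    """Permute each column of X independently; C and y are untouched.

    Every output column is a multiset-identical rearrangement of its
    input column, and the per-column permutations are drawn independently.
    """
    X = np.asarray(X)
    if X.size == 0:
        raise ConfigurationError("permute_features requires a non-empty matrix")
    # one independent permutation per column via argsort of iid keys
    order = np.argsort(rng.random(X.shape), axis=0)
    return np.take_along_axis(X, order, axis=0)


def empirical_p(null_scores, observed: float, *, smoothing: bool = False) -> float:
    """Exceedance p-value of ``observed`` within an empirical null."""
    null_scores = np.asarray(null_scores, dtype=float)
    exceed = int(np.sum(null_scores >= observed))
    if smoothing:
        return (1 + exceed) / (1 + null_scores.size)
    return exceed / null_scores.size


def permutation_test(
    X, C, y, pipeline_config: PipelineConfig, perm_config: PermutationConfig
) -> PermutationResult:
    """Empirical-null test of the cross-validated score.

    The observed score is the mean CV R^2 on the unpermuted data; each of
    the ``n_permutations`` null scores reruns the identical pipeline
    (same seed, same fold assignments) on column-permuted features.  The
    permutation generator is independent of the pipeline seed stream, so
    changing ``n_permutations`` never alters the observed score.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()

    n_fits = perm_config.n_permutations * (pipeline_config.k_folds + 1)
    if perm_config.max_model_fits is not None and n_fits > perm_config.max_model_fits:
        raise BudgetError(
            f"{n_fits} model fits exceed the budget of {perm_config.max_model_fits}; "
            "lower n_permutations or the predictor's tree count"
        )

    folds = fold_labels_for(y, pipeline_config, X.shape[0])
    observed = run_cv(X, C, y, pipeline_config, fold_assignments=folds)

    # keep per-permutation scoring lean: importances are irrelevant here
    null_config = replace(pipeline_config, compute_importances=False)

    rng = np.random.default_rng(perm_config.seed)
    null_scores = np.empty(perm_config.n_permutations)
    for i in range(perm_config.n_permutations):
        X_perm = permute_features(X, rng)
        null_scores[i] = run_cv(
            X_perm, C, y, null_config, fold_assignments=folds
        ).mean_score

    p = empirical_p(null_scores, observed.mean_score, smoothing=perm_config.smoothing)
    return PermutationResult(
        observed_score=observed.mean_score,
        null_scores=null_scores,
        p_value=p,
        config=perm_config,
    )
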