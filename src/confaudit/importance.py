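"""Impurity-based (Gini) feature importance, per fold and aggregated.

A forest's importance for a feature is the probability-weighted decrease
in node impurity over all splits on that feature, averaged over trees and
normalized so the importances sum to one.  Features never used in a split
get zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import ConfauditError, DataError

__all__ = ["ImportanceReport", "importance_from_forest", "aggregate_importance"]


def importance_from_forest(forest) -> np.ndarray:
    """Normalized Gini importances of a fitted forest.

    Degenerate forests in which no tree ever split (constant target)
    yield the uniform vector 1/p, with a warning, so the sum-to-one
    contract holds for every fitted forest.
    """
    if not hasattr(forest, "estimators_"):
        raise ConfauditError("importance_from_forest requires a fitted forest")
    imp = np.asarray(forest.feature_importances_, dtype=float)
    total = imp.sum()
    if total == 0.0:
        warnings.warn(
            "forest produced no splits; reporting uniform importances 1/p"
        )
        return np.full(imp.shape[0], 1.0 / imp.shape[0])
    return imp / total


@dataclass(frozen=True)
class ImportanceReport:
    """Mean, spread and ranking of per-fold importance vectors."""

    per_fold: np.ndarray  # k x p
    mean_importance: np.ndarray
    sd_importance: np.ndarray
    feature_names: tuple[str, ...]
    ranking: tuple[str, ...]  # by descending mean, ties broken by name

    def top_k(self, k: int = 10) -> pd.DataFrame:
        return self.to_frame().head(k)

    def to_frame(self) -> pd.DataFrame:
        order = [self.feature_names.index(name) for name in self.ranking]
        return pd.DataFrame(
            {
                "feature": list(self.ranking),
                "mean_importance": self.mean_importance[order],
                "sd_importance": self.sd_importance[order],
                "rank": np.arange(1, len(order) + 1),
            }
        )


def aggregate_importance(per_fold, feature_names) -> ImportanceReport:
    """Aggregate per-fold importance vectors into a ranked report.

    Mean and standard deviation are elementwise across folds; the ranking
    sorts by descending mean importance with lexicographic tie-break on
    the feature name.
    """
    per_fold = np.atleast_2d(np.asarray(per_fold, dtype=float))
    feature_names = tuple(feature_names)
    if per_fold.shape[1] != len(feature_names):
        raise DataError(
            f"importance vectors have {per_fold.shape[1]} entries but "
            f"{len(feature_names)} feature names were given"
        )
    if per_fold.shape[0] < 1:
        raise DataError("need at least one fold importance vector")
    mean = per_fold.mean(axis=0)
    sd = per_fold.std(axis=0)
    order = sorted(range(len(feature_names)), key=lambda j: (-mean[j], feature_names[j]))
    return ImportanceReport(
        per_fold=per_fold,
        mean_importance=mean,
        sd_importance=sd,
        feature_names=feature_names,
        ranking=tuple(feature_names[j] for j in order),
    )
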