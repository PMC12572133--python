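"""Condition grids: removal families x stratification, across targets.

The grid contrasts the cross-validated score under every requested
confound-removal family (including "none", i.e. confounds unused
anywhere) and stratification setting, all sharing one base seed so that
rows differ only in the condition.  The leakage diagnostic is the delta
of mean R^2 with versus without removal: a positive delta on data whose
features carry no target signal beyond the confounds is the signature of
confound leakage.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError
from .cv import PipelineConfig, run_cv
from .permutation import PermutationConfig, permutation_test
from .removal import REMOVAL_FAMILIES, RemovalModelSpec

__all__ = ["run_condition_grid", "leakage_delta", "batch_targets", "DEFAULT_FAMILIES"]

DEFAULT_FAMILIES = REMOVAL_FAMILIES  # linear, ridge, random_forest, extra_trees, none

_GRID_COLUMNS = [
    "target",
    "removal_family",
    "stratified",
    "mean_r2",
    "p_value",
    "n_folds",
    "seed",
    "error",
]


def _spec_for(family: str, base: PipelineConfig) -> RemovalModelSpec:
    if family in ("random_forest", "extra_trees"):
        hyper = {"random_state": base.seed}
        if family == base.removal.family:
            hyper = {**base.removal.hyperparameters, **hyper}
        return RemovalModelSpec(family, hyper)
    if family == base.removal.family:
        return base.removal
    return RemovalModelSpec(family)


def run_condition_grid(
    X,
    C,
    y,
    base_config: PipelineConfig,
    families=DEFAULT_FAMILIES,
    strat_options=(True, False),
    with_permutation: bool = False,
    perm_config: PermutationConfig | None = None,
    target_name: str = "target",
) -> pd.DataFrame:
    """One CV run (optionally plus a permutation test) per condition.

    Returns a tidy table with one row per (family, stratified) condition,
    sorted by those keys; a failing condition is recorded in its row's
    ``error`` column instead of aborting the grid.
    """
    families = list(families)
    if not families:
        raise ConfigurationError("families must be non-empty")
    if len(set(families)) != len(families):
        raise ConfigurationError(f"duplicate removal families: {families}")
    if with_permutation and perm_config is None:
        perm_config = PermutationConfig(seed=base_config.seed)

    rows = []
    for family in sorted(families):
        for stratified in sorted(set(bool(s) for s in strat_options)):
            config = replace(
                base_config,
                removal=_spec_for(family, base_config),
                stratify=bool(stratified),
                compute_importances=False,
            )
            row = {
                "target": target_name,
                "removal_family": family,
                "stratified": bool(stratified),
                "mean_r2": np.nan,
                "p_value": np.nan,
                "n_folds": config.k_folds,
                "seed": config.seed,
                "error": "",
            }
            try:
                if with_permutation:
                    res = permutation_test(X, C, y, config, perm_config)
                    row["mean_r2"] = res.observed_score
                    row["p_value"] = res.p_value
                else:
                    row["mean_r2"] = run_cv(X, C, y, config).mean_score
            except Exception as exc:
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)

    return pd.DataFrame(rows, columns=_GRID_COLUMNS)


def leakage_delta(result_with_cr: float, result_without_cr: float) -> float:
    """Mean R^2 with removal minus mean R^2 without removal.

    A positive delta on data whose features carry no target signal
    beyond the confounds flags suspected confound leakage.
    """
    return float(result_with_cr) - float(result_without_cr)


def batch_targets(X, C, Y: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """One cross-validation summary row per target column of ``Y``.

    Flags every target with positive mean R^2 and with mean R^2 above
    0.1, the conventional threshold for a reasonable model fit in this
    kind of audit.  Per-target failures are tagged, not fatal.
    """
    if not isinstance(Y, pd.DataFrame):
        raise ConfigurationError("Y must be a DataFrame with named target columns")
    rows = []
    for name in Y.columns:
        row = {
            "target": name,
            "mean_r2": np.nan,
            "positive_r2": False,
            "r2_above_0.1": False,
            "n_folds": config.k_folds,
            "seed": config.seed,
            "error": "",
        }
        try:
            result = run_cv(X, C, Y[name].to_numpy(), config)
            row["mean_r2"] = result.mean_score
            row["positive_r2"] = result.mean_score > 0
            row["r2_above_0.1"] = result.mean_score > 0.1
        except Exception as exc:
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
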