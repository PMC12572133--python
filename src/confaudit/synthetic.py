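"""Synthetic confounded tabular data.

Generates feature / confound / target tables with controlled
confound-target correlation, per-feature confound and target loadings, and
the distributional pathologies (skew, limited numeric precision) under
which residualization-based confound removal is known to leak confound
information into nonlinear predictors.

The confound panel mimics a typical demographic triple: one continuous
column (age-like), one binary column (sex-like) and one 4-level ordinal
column (education-like).  The target is built from the first confound so
that ``corr(C[:, 0], y)`` converges to ``rho_confound_target`` as the
sample grows; each feature is a linear mix of the (standardized) confounds
plus an optional direct target loading plus Gaussian noise, transformed to
the requested marginal distribution and finally rounded to the requested
precision.  Loadings are therefore defined on the latent (pre-transform)
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._exceptions import ConfigurationError, DataError

__all__ = [
    "GeneratorConfig",
    "Dataset",
    "generate_dataset",
    "leakage_scenario",
    "pure_noise_scenario",
    "signal_scenario",
]

FEATURE_DISTRIBUTIONS = ("gaussian", "lognormal", "discretized")

# Education-category proportions of a mixed adult cohort (secondary school /
# vocational training / university-entrance diploma / university degree).
_EDUCATION_PROBS = np.array([0.035, 0.268, 0.299, 0.398])
_EDUCATION_PROBS = _EDUCATION_PROBS / _EDUCATION_PROBS.sum()


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic generator.

    Parameters
    ----------
    n_samples, n_features, n_confounds:
        Shape of the generated tables.
    rho_confound_target:
        Asymptotic correlation between the first confound and the target,
        in [-1, 1].
    confound_loading:
        Strength of the confound mix in every feature (latent scale);
        0 removes all confound signal from the features.
    target_loading:
        Strength of the direct target signal in every feature; 0 gives the
        pure-leakage regime in which features carry no target information
        beyond the confounds.
    noise_sd:
        Standard deviation of the independent feature noise (> 0).
    feature_distribution:
        Marginal transform applied to the latent features: ``gaussian``
        (identity), ``lognormal`` (exponentiation) or ``discretized``
        (rounding to integers).
    precision_digits:
        If not None, features are rounded to this many decimal digits
        (round-half-even), emulating limited-precision measurements.
    seed:
        Master seed; identical config + seed gives bit-identical output.
    """

    n_samples: int = 230
    n_features: int = 100
    n_confounds: int = 3
    rho_confound_target: float = 0.0
    confound_loading: float = 1.0
    target_loading: float = 0.0
    noise_sd: float = 1.0
    feature_distribution: str = "gaussian"
    precision_digits: int | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples", "n_features", "n_confounds"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        if not -1.0 <= self.rho_confound_target <= 1.0:
            raise ConfigurationError(
                f"rho_confound_target must lie in [-1, 1], got {self.rho_confound_target!r}"
            )
        if self.confound_loading < 0:
            raise ConfigurationError(
                f"confound_loading must be nonnegative, got {self.confound_loading!r}"
            )
        if self.target_loading < 0:
            raise ConfigurationError(
                f"target_loading must be nonnegative, got {self.target_loading!r}"
            )
        if not self.noise_sd > 0:
            raise ConfigurationError(f"noise_sd must be positive, got {self.noise_sd!r}")
        if self.feature_distribution not in FEATURE_DISTRIBUTIONS:
            raise ConfigurationError(
                f"feature_distribution must be one of {FEATURE_DISTRIBUTIONS}, "
                f"got {self.feature_distribution!r}"
            )
        if self.precision_digits is not None and (
            not isinstance(self.precision_digits, (int, np.integer)) or self.precision_digits < 0
        ):
            raise ConfigurationError(
                f"precision_digits must be a nonnegative integer or None, "
                f"got {self.precision_digits!r}"
            )


@dataclass(frozen=True)
class Dataset:
    """Row-aligned feature matrix, confound matrix and target vector."""

    X: np.ndarray
    C: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...] = field(default=())
    confound_names: tuple[str, ...] = field(default=())
    config: GeneratorConfig | None = None

    def __post_init__(self):
        if self.X.ndim != 2 or self.C.ndim != 2 or self.y.ndim != 1:
            raise DataError("X and C must be 2-D, y must be 1-D")
        n = self.X.shape[0]
        if self.C.shape[0] != n or self.y.shape[0] != n:
            raise DataError(
                f"row counts differ: X has {n}, C has {self.C.shape[0]}, y has {self.y.shape[0]}"
            )
        for name, arr in (("X", self.X), ("C", self.C), ("y", self.y)):
            if not np.all(np.isfinite(arr)):
                raise DataError(f"{name} contains missing or non-finite values")
        names = self.feature_names + self.confound_names
        if len(set(names)) != len(names):
            raise DataError("feature and confound column names must be unique")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_confounds(self) -> int:
        return self.C.shape[1]


def _confound_names(q: int) -> tuple[str, ...]:
    base = ["age", "sex", "education"]
    if q <= 3:
        return tuple(base[:q])
    return tuple(base + [f"confound_{i}" for i in range(3, q)])


def _draw_confounds(rng: np.random.Generator, n: int, q: int) -> np.ndarray:
    """Demographic-style confound panel: continuous, binary, 4-level ordinal."""
    cols = []
    for j in range(q):
        if j == 0:
            cols.append(rng.standard_normal(n))
        elif j == 1:
            cols.append(rng.binomial(1, 0.5, size=n).astype(float))
        elif j == 2:
            cols.append(rng.choice(4, size=n, p=_EDUCATION_PROBS).astype(float))
        else:
            cols.append(rng.standard_normal(n))
    return np.column_stack(cols)


def _standardize_columns(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (M - mu) / sd


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """Draw one dataset under ``config``; deterministic in (config, seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p, q = config.n_samples, config.n_features, config.n_confounds

    C = _draw_confounds(rng, n, q)
    C_std = _standardize_columns(C)

    rho = config.rho_confound_target
    y = rho * C_std[:, 0] + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)

    # Per-feature unit-norm mixing weights over the standardized confounds keep
    # confound_loading interpretable as the latent-scale signal amplitude.
    W = rng.standard_normal((p, q))
    W /= np.linalg.norm(W, axis=1, keepdims=True)

    latent = (
        config.confound_loading * (C_std @ W.T)
        + config.target_loading * y[:, None]
        + config.noise_sd * rng.standard_normal((n, p))
    )

    if config.feature_distribution == "lognormal":
        X = np.exp(latent)
    elif config.feature_distribution == "discretized":
        X = np.rint(latent)
    else:
        X = latent

    if config.precision_digits is not None:
        X = np.round(X, config.precision_digits)  # numpy rounds half to even

    return Dataset(
        X=X,
        C=C,
        y=y,
        feature_names=tuple(f"feature_{j:03d}" for j in range(p)),
        confound_names=_confound_names(q),
        config=config,
    )


#: Preset reproducing the leakage-prone regime: a moderately strong
#: confound-target correlation, many skewed limited-precision features, and
#: no direct feature-target signal.  In this regime cross-validated R^2 is
#: expected to be *higher* with confound removal than without it.
LEAKAGE_PRESET = GeneratorConfig(
    n_samples=230,
    n_features=100,
    n_confounds=3,
    rho_confound_target=0.65,
    confound_loading=0.5,
    target_loading=0.0,
    noise_sd=2.0,
    feature_distribution="lognormal",
    precision_digits=0,
)

#: Preset for the global null: features independent of confounds and target.
PURE_NOISE_PRESET = GeneratorConfig(
    n_samples=200,
    n_features=20,
    n_confounds=3,
    rho_confound_target=0.3,
    confound_loading=0.0,
    target_loading=0.0,
    noise_sd=1.0,
    feature_distribution="gaussian",
    precision_digits=None,
)


#: Preset with genuine feature-target signal: identical to the pure-noise
#: preset except for a direct target loading calibrated so that a
#: 25-tree forest reaches out-of-sample R^2 of about 0.3 at this shape
#: (n=200, p=20).  Used to exercise the power of the permutation test.
SIGNAL_PRESET = replace(PURE_NOISE_PRESET, target_loading=0.23)


def signal_scenario(seed: int) -> Dataset:
    """Dataset whose features carry genuine target signal (OOS R^2 ~ 0.3)."""
    return generate_dataset(replace(SIGNAL_PRESET, seed=seed))


def leakage_scenario(seed: int) -> Dataset:
    """Dataset in which confound removal is expected to raise CV R^2."""
    return generate_dataset(replace(LEAKAGE_PRESET, seed=seed))


def pure_noise_scenario(seed: int) -> Dataset:
    """Dataset whose features carry no information about confounds or target."""
    return generate_dataset(replace(PURE_NOISE_PRESET, seed=seed))
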