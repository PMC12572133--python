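"""Table readers/writers, run configuration and result serialization.

All tabular I/O is comma-delimited UTF-8 text with a header row and a
``sample_id`` column as the join key; the three tables of a run
(features, confounds, targets) are aligned on sorted sample_id at load
time.  Missing values are errors, not imputed — every downstream
statistic assumes complete data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import sklearn
import yaml

from ._exceptions import ConfigurationError, DataError
from .cv import PipelineConfig
from .permutation import PermutationConfig
from .removal import RemovalModelSpec

__all__ = ["RunConfig", "read_table", "load_aligned", "write_results"]

SAMPLE_ID = "sample_id"


def read_table(path) -> pd.DataFrame:
    """Read one CSV table indexed by a unique ``sample_id`` column.

    Every non-index cell must parse as a number; the error for a bad cell
    names its row and column.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"table not found: {path}")
    df = pd.read_csv(path)
    if SAMPLE_ID not in df.columns:
        raise DataError(f"{path}: required column '{SAMPLE_ID}' is missing")
    dup = df[SAMPLE_ID][df[SAMPLE_ID].duplicated()].tolist()
    if dup:
        raise DataError(f"{path}: duplicated sample_id values: {dup}")
    df = df.set_index(SAMPLE_ID)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        if bad:
            raise DataError(
                f"{path}: non-numeric value in column '{col}' at sample_id {bad[:5]}"
            )
        if coerced.isna().any():
            missing = df.index[coerced.isna()].tolist()
            raise DataError(
                f"{path}: missing values in column '{col}' at sample_id {missing[:5]}"
            )
        df[col] = coerced
    return df


def load_aligned(features_path, confounds_path, targets_path):
    """Load the three run tables and align their rows on sorted sample_id."""
    X = read_table(features_path)
    C = read_table(confounds_path)
    Y = read_table(targets_path)
    ids = set(X.index)
    if set(C.index) != ids or set(Y.index) != ids:
        only = {
            "features_only": sorted(ids - set(C.index) | ids - set(Y.index))[:5],
            "confounds_only": sorted(set(C.index) - ids)[:5],
            "targets_only": sorted(set(Y.index) - ids)[:5],
        }
        raise DataError(f"sample_id sets differ across tables: {only}")
    order = sorted(ids)
    return X.loc[order], C.loc[order], Y.loc[order]


@dataclass(frozen=True)
class RunConfig:
    """Full, file-round-trippable description of one audit run."""

    features: str = "features.csv"
    confounds: str = "confounds.csv"
    targets: str = "targets.csv"
    target_column: str | None = None
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    grid_families: tuple[str, ...] = ("linear", "ridge", "random_forest", "extra_trees", "none")
    out_dir: str = "results"
    log_level: str = "INFO"
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["grid_families"] = list(self.grid_families)
        d["pipeline"]["removal"] = dataclasses.asdict(self.pipeline.removal)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        pipeline = dict(d.pop("pipeline", {}))
        removal = pipeline.pop("removal", None)
        if removal is not None:
            pipeline["removal"] = RemovalModelSpec(**removal)
        permutation = d.pop("permutation", {})
        families = d.pop("grid_families", None)
        kwargs: dict[str, Any] = dict(d)
        kwargs["pipeline"] = PipelineConfig(**pipeline)
        kwargs["permutation"] = PermutationConfig(**permutation)
        if families is not None:
            kwargs["grid_families"] = tuple(families)
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigurationError(f"invalid run config: {exc}") from exc

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(results: dict[str, Any], out_dir, config: RunConfig | None = None) -> dict:
    """Write a deterministic file set plus a provenance manifest.

    Recognized keys of ``results``: ``cv`` (CVResult-like mapping or
    dataclass) -> results.json; ``grid`` (DataFrame) -> grid.csv;
    ``importance`` (DataFrame) -> importance.csv; ``null_scores``
    (array) -> null.csv.  Returns the manifest.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise DataError(f"output directory not writable: {out_dir} ({exc})") from exc

    manifest: dict[str, Any] = {
        "files": [],
        "seed": config.seed if config is not None else None,
        "config_hash": config.content_hash() if config is not None else None,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }

    def _emit(name: str, writer) -> None:
        writer(out_dir / name)
        manifest["files"].append(name)

    if "cv" in results:
        payload = _jsonable(results["cv"])
        if config is not None:
            payload = {"result": payload, "seed": config.seed, "config_hash": config.content_hash()}
        _emit("results.json", lambda p: p.write_text(json.dumps(payload, indent=2, sort_keys=True)))
    if "grid" in results:
        _emit("grid.csv", lambda p: results["grid"].to_csv(p, index=False))
    if "importance" in results:
        _emit("importance.csv", lambda p: results["importance"].to_csv(p, index=False))
    if "null_scores" in results:
        null = np.asarray(results["null_scores"])
        _emit(
            "null.csv",
            lambda p: pd.DataFrame({"null_score": null}).to_csv(p, index=False),
        )

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
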