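"""Table I/O, run configuration and result serialization.

Feature matrices travel as delimited text (CSV/TSV).  The canonical
in-memory orientation is samples-as-rows; metabolomics exports frequently
store features horizontally (one row per feature), which callers request
explicitly via ``orientation="features_as_rows"`` — near-square matrices
make silent auto-detection unsafe.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("swarmselect")

__all__ = [
    "FeatureTable",
    "TargetTable",
    "RunConfig",
    "read_table",
    "write_table",
    "write_results",
    "load_config",
]


@dataclass
class FeatureTable:
    """An n-samples x m-features numeric matrix with axis labels."""

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D (samples x features)")
        n, m = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if m < 1:
            raise ValueError("need at least 1 feature")
        if len(self.feature_names) != m:
            raise ValueError("feature_names length does not match matrix width")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match matrix height")
        if len(set(self.feature_names)) != m:
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class TargetTable:
    """Continuous response columns aligned with a :class:`FeatureTable`."""

    values: np.ndarray
    target_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if len(self.target_names) != self.values.shape[1]:
            raise ValueError("target_names length does not match matrix width")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("target matrix contains non-finite values")
        for j, name in enumerate(self.target_names):
            if np.ptp(self.values[:, j]) == 0:
                raise ValueError(f"target column {name!r} is constant")

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.target_names.index(name)
        except ValueError:
            raise KeyError(f"no target column named {name!r}") from None
        return self.values[:, j]


@dataclass
class RunConfig:
    """All tunables of a two-stage selection run.

    Optimizer defaults follow the published CMOPSO parameterization:
    T = 300 iterations, swarm of 100, archive capacity 50, a 20x20
    objective-space grid, inertia decreasing 0.9 -> 0.4 and acceleration
    ramps c1: 2.75 -> 1.25, c2: 0.5 -> 2.25.
    """

    filter_method: str = "mrmr"  # mrmr | pearson | spearman
    sfs_step: float = 0.01  # int = absolute, float in (0,1) = fraction of m
    cv_folds: int = 10
    pls_components: int = 2
    optimizer: str = "cmopso"  # cmopso | mopso
    iterations: int = 300
    pop_size: int = 100
    archive_size: int = 50
    mesh_divisions: int = 20
    w_max: float = 0.9
    w_min: float = 0.4
    c1i: float = 1.25
    c1f: float = 2.75
    c2i: float = 2.25
    c2f: float = 0.5
    decode_threshold: float = 0.6
    literal_c2: bool = False
    pooled_rmse: bool = False
    relevance_only: bool = False
    n_bins: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.filter_method not in ("mrmr", "pearson", "spearman"):
            raise ValueError(f"unknown filter method {self.filter_method!r}")
        if self.optimizer not in ("cmopso", "mopso"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if not (self.w_max > self.w_min):
            raise ValueError("w_max must exceed w_min")
        if self.archive_size < 1:
            raise ValueError("archive_size must be >= 1")
        if not (0.0 < self.decode_threshold < 1.0):
            raise ValueError("decode_threshold must lie in (0, 1)")
        if self.sfs_step <= 0:
            raise ValueError("sfs_step must be positive")
        for name in ("cv_folds", "pls_components", "iterations", "pop_size",
                     "mesh_divisions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    def resolve_step(self, m: int) -> int:
        """Turn a fractional prefix step into an absolute one for m features."""
        s = self.sfs_step
        if 0 < s < 1:
            return max(1, round(s * m))
        return max(1, int(round(s)))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") > first.count(",") else ","


def read_table(
    path: str | Path,
    orientation: str = "samples_as_rows",
    target_columns: Sequence[str] = (),
) -> tuple[FeatureTable | None, TargetTable | None]:
    """Load a delimited numeric table and split off target columns.

    The delimiter (comma or tab) is sniffed from the first line.  A
    non-numeric first column is taken as the axis labels.  Rows (samples)
    containing missing values are dropped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if orientation not in ("samples_as_rows", "features_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    # first column as labels when it is non-numeric
    first = df.columns[0]
    if df[first].dtype == object:
        df = df.set_index(first)
    else:
        df.index = pd.Index([f"row{i}" for i in range(len(df))])
    bad = df.apply(pd.to_numeric, errors="coerce")
    newly_bad = bad.isna() & df.notna()
    if newly_bad.any().any():
        i, j = np.argwhere(newly_bad.values)[0]
        raise ValueError(
            f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    df = bad

    if orientation == "features_as_rows":
        df = df.T

    n_before = len(df)
    df = df.dropna(axis=0, how="any")
    dropped = n_before - len(df)
    if dropped:
        logger.info("dropped %d sample row(s) with missing values", dropped)

    for col in target_columns:
        if col not in df.columns:
            raise KeyError(f"target column {col!r} not found in {path.name}")

    target: TargetTable | None = None
    if target_columns:
        target = TargetTable(
            values=df[list(target_columns)].to_numpy(float),
            target_names=list(target_columns),
        )
        df = df.drop(columns=list(target_columns))
    if df.shape[1] == 0:
        return None, target  # file held targets only
    features = FeatureTable(
        values=df.to_numpy(float),
        feature_names=[str(c) for c in df.columns],
        sample_ids=[str(i) for i in df.index],
    )
    return features, target


def write_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV, lossless for finite doubles."""
    df = pd.DataFrame(table.values, index=table.sample_ids,
                      columns=table.feature_names)
    df.index.name = "sample_id"
    df.to_csv(path)  # pandas writes repr(float): round-trips exactly


def write_results(result, out_dir: str | Path) -> dict:
    """Serialize a pipeline result bundle; returns a manifest of files.

    Writes the Stage-1 prefix trace, the Pareto front (size, RMSE and the
    member's feature names) and a JSON manifest embedding the RunConfig,
    sufficient to rerun the pipeline and reproduce the front exactly.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {out}: {e}") from e

    trace_path = out / "candidate_trace.csv"
    pd.DataFrame(result.candidate.trace,
                 columns=["prefix_size", "rmse"]).to_csv(trace_path, index=False)

    front_path = out / "pareto_front.csv"
    rows = []
    for entry, metrics in zip(result.front, result.metrics_per_front_member):
        names = ";".join(result.feature_names(entry))
        rows.append({
            "n_features": entry.objectives[0],
            "rmse": repr(float(entry.objectives[1])),
            "r2": repr(float(metrics.r2)),
            "mae": repr(float(metrics.mae)),
            "feature_names": names,
        })
    pd.DataFrame(
        rows, columns=["n_features", "rmse", "r2", "mae", "feature_names"]
    ).to_csv(front_path, index=False)

    manifest = {
        "config": result.config_echo.to_dict(),
        "candidate_size": len(result.candidate.feature_indices),
        "candidate_rmse": float(result.candidate.rmse),
        "files": {
            "candidate_trace": trace_path.name,
            "pareto_front": front_path.name,
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["files"]["manifest"] = manifest_path.name
    return manifest


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML or the JSON manifest of a previous run."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if "config" in doc and isinstance(doc["config"], dict):
        doc = doc["config"]
    return RunConfig.from_dict(doc)
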