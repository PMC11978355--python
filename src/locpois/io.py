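"""Dataset reading/writing, descriptive statistics, and run configuration."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataValidationError
from .likelihood import CountDataset

__all__ = ["RunConfig", "read_count_dataset", "write_count_dataset", "describe", "load_config"]

#: repr-level float formatting keeps written output deterministic and lossless
FLOAT_FORMAT = "%.17g"


def read_count_dataset(path, response: str, predictors, sep: str = ",") -> CountDataset:
    """Read a delimited text file with a header into a validated CountDataset.

    The response column must parse to non-negative integers and the predictor
    columns to finite reals; offending rows are reported by number.
    """
    predictors = list(predictors)
    if response in predictors:
        raise ConfigurationError(
            f"response column {response!r} also listed among the predictors"
        )
    if len(set(predictors)) != len(predictors):
        raise ConfigurationError(f"duplicated predictor columns in {predictors}")
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in [response, *predictors] if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"columns {missing} not found in header {list(df.columns)}"
        )
    sub = df[[response, *predictors]]
    if sub.isna().any().any():
        bad_rows = sub.index[sub.isna().any(axis=1)].tolist()
        raise DataValidationError(f"missing values in rows {bad_rows}")
    yf = pd.to_numeric(sub[response], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(yf)) or np.any(yf < 0) or np.any(yf != np.rint(yf)):
        bad = int(np.flatnonzero(~np.isfinite(yf) | (yf < 0) | (yf != np.rint(yf)))[0])
        raise DataValidationError(
            f"response column {response!r} must hold non-negative integers; "
            f"row {bad} has value {sub[response].iloc[bad]!r}"
        )
    X = sub[predictors].to_numpy(dtype=float)
    if np.any(~np.isfinite(X)):
        bad = int(np.flatnonzero(~np.isfinite(X).all(axis=1))[0])
        raise DataValidationError(f"non-finite predictor value in row {bad}")
    return CountDataset(y=yf.astype(np.int64), X=X, names=tuple(predictors))


def write_count_dataset(data: CountDataset, path, response: str = "y", sep: str = ",") -> None:
    """Write a CountDataset as delimited text at full float precision."""
    df = pd.DataFrame({response: data.y})
    for j, name in enumerate(data.names):
        df[name] = data.X[:, j]
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FORMAT)


def describe(data: CountDataset) -> pd.DataFrame:
    """Per-column mean, min, max and sample standard deviation (n-1 denominator)."""
    if data.n < 2:
        raise DataValidationError("need at least 2 rows to describe")
    cols = {"y": data.y.astype(float)}
    cols.update({name: data.X[:, j] for j, name in enumerate(data.names)})
    rows = [
        {
            "variable": name,
            "mean": float(np.mean(v)),
            "min": float(np.min(v)),
            "max": float(np.max(v)),
            "sd": float(np.std(v, ddof=1)),
        }
        for name, v in cols.items()
    ]
    return pd.DataFrame(rows).set_index("variable")


@dataclass
class RunConfig:
    """Resolved run configuration for the command-line interface."""

    input: str | None = None
    response: str = "y"
    predictors: list = field(default_factory=list)
    kernel_family: str = "gaussian"
    bandwidths: list | None = None
    bandwidth_grid: list | None = None
    bandwidth_mode: str = "per_predictor"
    epsilon: float = 1e-6
    max_iter: int = 100
    safeguard: bool = True
    ridge: float = 1e-10
    output: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.response in self.predictors:
            raise ConfigurationError(
                f"response column {self.response!r} also listed among the predictors"
            )


_CONFIG_KEYS = {
    "input": "input",
    "response": "response",
    "predictors": "predictors",
    "kernel.family": "kernel_family",
    "kernel.bandwidths": "bandwidths",
    "bandwidth.grid": "bandwidth_grid",
    "bandwidth.mode": "bandwidth_mode",
    "fit.epsilon": "epsilon",
    "fit.max_iter": "max_iter",
    "fit.safeguard": "safeguard",
    "fit.ridge": "ridge",
    "output": "output",
    "seed": "seed",
    "log_level": "log_level",
}


def load_config(path, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration; explicit overrides (CLI flags) win.

    Nested YAML sections map to dotted keys, e.g. ``kernel: {family: gaussian}``
    is ``kernel.family``.
    """
    raw = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        flat = {}
        for key, value in doc.items():
            if isinstance(value, dict):
                for sub, v in value.items():
                    flat[f"{key}.{sub}"] = v
            else:
                flat[key] = value
        for key, value in flat.items():
            if key not in _CONFIG_KEYS:
                raise ConfigurationError(f"unknown config key {key!r}")
            raw[_CONFIG_KEYS[key]] = value
    for key, value in (overrides or {}).items():
        if value is not None:
            raw[key] = value
    return RunConfig(**raw)
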