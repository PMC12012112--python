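"""File formats: trajectory CSV with JSON sidecar metadata, indicator-series
and results tables, and the YAML run configuration.

Trajectories are stored as plain CSV (step, t, k, x) with floats serialized
at full round-trip precision ('%.17g'), plus a ``<name>.meta.json`` sidecar
carrying provenance (model, alpha, gamma_N, dt, epsilon, x0, seed, scheme,
truncation indices).  write -> read is bit-exact.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .experiments import ExperimentSpec
from .integrate import Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_ew_series",
    "write_results",
    "ConfigError",
    "load_config",
    "save_config",
]

_FLOAT_FMT = "%.17g"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_trajectory(traj: Trajectory, path) -> Path:
    """Write a trajectory to CSV + JSON sidecar; returns the CSV path."""
    path = Path(path)
    n = traj.n_steps
    df = pd.DataFrame(
        {
            "step": np.arange(n + 1),
            "t": traj.times,
            "k": np.concatenate([[np.nan], traj.k_schedule]),  # k used for step j
            "x": traj.values,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "model": traj.model_name,
        "alpha": traj.alpha,
        "gamma_N": traj.gamma_N,
        "dt": traj.dt,
        "epsilon": traj.epsilon,
        "x0": traj.x0,
        "scheme": traj.scheme,
        "seed": _jsonable(traj.seed),
        "truncated_at": traj.truncated_at,
        "diverged_at": traj.diverged_at,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_trajectory(path) -> Trajectory:
    """Read back a trajectory written by :func:`write_trajectory` bit-exactly."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta = json.loads(_sidecar(path).read_text())
    values = df["x"].to_numpy()
    return Trajectory(
        times=df["t"].to_numpy(),
        values=values,
        k_schedule=df["k"].to_numpy()[1:],
        dt=meta["dt"],
        model_name=meta["model"],
        alpha=meta["alpha"],
        gamma_N=meta["gamma_N"],
        scheme=meta["scheme"],
        x0=meta["x0"],
        epsilon=meta["epsilon"],
        seed=tuple(meta["seed"]) if isinstance(meta["seed"], list) else meta["seed"],
        truncated_at=meta["truncated_at"],
        diverged_at=meta["diverged_at"],
    )


def write_ew_series(series, path, extra_meta: dict | None = None) -> Path:
    """Write an :class:`EWSeries` to CSV with a JSON sidecar (window, stride,
    method)."""
    path = Path(path)
    series.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {"window": series.window, "stride": series.stride, "method": series.method}
    meta.update(extra_meta or {})
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def write_results(df: pd.DataFrame, path, summary: dict | None = None) -> Path:
    """Write a results table to CSV; optional summary dict goes to a
    ``<name>.summary.json`` next to it."""
    path = Path(path)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    if summary is not None:
        path.with_suffix(".summary.json").write_text(
            json.dumps(_jsonable(summary), indent=2)
        )
    return path


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending field."""


_SPEC_FIELDS = {f.name: f for f in dataclasses.fields(ExperimentSpec)}
_TUPLE_FIELDS = {"alphas", "k_values", "divergence_alphas"}


def load_config(path) -> ExperimentSpec:
    """Load an :class:`ExperimentSpec` from YAML.  Unknown keys are rejected
    with the offending field named."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    unknown = set(raw) - set(_SPEC_FIELDS)
    if unknown:
        raise ConfigError(f"unknown config field(s): {', '.join(sorted(unknown))}")
    if "protocol" not in raw:
        raise ConfigError("missing required field: protocol")
    kw = {}
    for name, value in raw.items():
        if name in _TUPLE_FIELDS:
            if not isinstance(value, (list, tuple)):
                raise ConfigError(f"field {name} must be a list")
            value = tuple(float(v) for v in value)
        kw[name] = value
    try:
        return ExperimentSpec(**kw)
    except (TypeError, ValueError) as e:
        raise ConfigError(str(e)) from e


def save_config(spec: ExperimentSpec, path) -> Path:
    """Write the fully resolved configuration (every field, defaults
    included) as YAML.  load_config(save_config(spec)) == spec."""
    path = Path(path)
    d = dataclasses.asdict(spec)
    d = {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}
    path.write_text(yaml.safe_dump(d, sort_keys=False))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
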