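"""Scripted simulation studies.

Three seeded protocols, each returning tidy :class:`pandas.DataFrame` tables:

* :func:`run_equilibrium` — constant-k runs over a k-grid; each replicate
  pools thinned stationary states from several trajectories, fits the SaS
  scale and compares it with the stationary theory gamma_X.
* :func:`run_nonequilibrium` — equilibrate, then ramp k linearly toward the
  bifurcation while tracking rolling-window indicators: the applied
  early-warning setting.
* :func:`run_divergence_demo` — constant k, expanding-window running variance
  vs running gamma_hat: the false-positive demonstration (running variance
  fails to settle under heavy tails; gamma_hat settles for every alpha).

Seeding: every noise sequence is seeded by a tuple (master_seed, replicate,
trajectory).  The tuple never includes alpha or k, so the same base draws
drive every alpha (extreme events hit at the same indices) and, within a
replicate, the identical increments are replayed across the whole k-grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dynamics import PotentialModel, gamma_x_limit, linearized_rate
from .estimate import (
    expanding_ews,
    fit_sas_ecf,
    fit_sas_quantile,
    lag1_autocorr,
    rolling_ews,
    smooth_series,
    variance_estimator,
)
from .integrate import (
    SimConfig,
    Trajectory,
    k_ramp,
    make_noise_increments,
    tamed_euler_maruyama,
)

__all__ = [
    "ExperimentSpec",
    "run_equilibrium",
    "run_nonequilibrium",
    "summarize_nonequilibrium",
    "run_divergence_demo",
    "divergence_summary",
]

PROTOCOLS = ("equilibrium", "nonequilibrium", "divergence")


@dataclass(frozen=True)
class ExperimentSpec:
    """Protocol configuration.  Defaults reproduce the study conditions:
    dt = 0.004, gamma_N = 0.1, x0 = 0.5, alphas {2, 1.8, 1.5, 1.3};
    equilibrium: k in {100, 10, 1, 0.1, 0.01}, 100 replicates of 5
    trajectories x 10 000 steps, 70 thinned points per trajectory;
    non-equilibrium: 15 trajectories, 10 000 equilibration steps + 50 000
    ramp steps (k: 5 -> 0 by 0.0001), window 300 / stride 150, 100-point
    smoothing; divergence: 100 trajectories at k = 1, estimates every 300
    steps."""

    protocol: str
    model: str = "ou"
    alphas: tuple[float, ...] = (2.0, 1.8, 1.5, 1.3)
    gamma_N: float = 0.1
    dt: float = 0.004
    epsilon: float | None = None
    x0: float = 0.5
    master_seed: int = 0
    fix_alpha: bool = False  # if True, fix alpha at the driving value when fitting
    fit_method: str = "quantile"
    # equilibrium protocol
    k_values: tuple[float, ...] = (100.0, 10.0, 1.0, 0.1, 0.01)
    n_replicates: int = 100
    trajectories_per_estimate: int = 5
    n_steps: int = 10_000
    burn_in_fraction: float = 0.3
    points_per_trajectory: int = 70
    # non-equilibrium protocol
    n_trajectories: int = 15
    equilibration_steps: int = 10_000
    ramp_start: float = 5.0
    ramp_end: float = 0.0
    ramp_step: float = 1e-4
    window: int = 300
    stride: int = 150
    smooth_window: int = 100
    # divergence protocol
    divergence_alphas: tuple[float, ...] = (2.0, 1.3)
    divergence_k: float = 1.0
    divergence_n_traj: int = 100
    divergence_steps: int = 10_000
    divergence_every: int = 300

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"protocol must be one of {PROTOCOLS}, got {self.protocol!r}")
        if self.model not in ("ou", "fold"):
            raise ValueError(f"model must be 'ou' or 'fold', got {self.model!r}")
        if self.fit_method not in ("quantile", "ecf"):
            raise ValueError(f"fit_method must be 'quantile' or 'ecf'")

    def with_(self, **kw) -> "ExperimentSpec":
        return replace(self, **kw)


def _theory_gamma(model: str, k: float, alpha: float, gamma_N: float) -> float:
    """Stationary gamma_X; the fold model enters via its linearized OU rate."""
    rate = k if model == "ou" else linearized_rate(k)
    return gamma_x_limit(rate, alpha, gamma_N)


def _fit(x, method: str, fixed_alpha):
    if method == "ecf":
        return fit_sas_ecf(x, fixed_alpha=fixed_alpha)
    return fit_sas_quantile(x, fixed_alpha=fixed_alpha)


def _thin_states(traj: Trajectory, burn_in: int, n_points: int) -> np.ndarray:
    """n_points evenly spaced post-burn-in states (fewer if the trajectory
    was truncated early)."""
    last = traj.n_valid_steps
    if last <= burn_in + 1:
        return np.empty(0)
    idx = np.unique(np.round(np.linspace(burn_in + 1, last, n_points)).astype(int))
    return traj.values[idx]


def _slice_from(traj: Trajectory, start: int) -> Trajectory:
    """View of a trajectory from step ``start`` onward, re-indexed to 0."""
    trunc = None
    div = None
    if traj.truncated_at is not None:
        if traj.truncated_at <= start:
            raise ValueError("trajectory ended before the requested slice")
        trunc = traj.truncated_at - start
    if traj.diverged_at is not None:
        if traj.diverged_at <= start:
            raise ValueError("trajectory diverged before the requested slice")
        div = traj.diverged_at - start
    n = traj.n_steps - start
    return Trajectory(
        times=np.arange(n + 1) * traj.dt,
        values=traj.values[start:],
        k_schedule=traj.k_schedule[start:],
        dt=traj.dt,
        model_name=traj.model_name,
        alpha=traj.alpha,
        gamma_N=traj.gamma_N,
        scheme=traj.scheme,
        x0=float(traj.values[start]),
        epsilon=traj.epsilon,
        seed=traj.seed,
        truncated_at=trunc,
        diverged_at=div,
    )


def run_equilibrium(spec: ExperimentSpec) -> pd.DataFrame:
    """Constant-k protocol.  One row per (alpha, k, replicate).

    Within a replicate the same noise sequences are replayed across the
    whole k-grid, and replicate seeds are alpha-independent, so differences
    along k and across alpha reflect the drift response, not the noise draw.
    Fold replicates in which any trajectory escaped its basin are flagged
    ``stopped`` (their estimate, if computable from pre-escape states, is
    still recorded) — flagged rows should be excluded from theory summaries.
    """
    if spec.protocol != "equilibrium":
        raise ValueError(f"spec.protocol is {spec.protocol!r}, expected 'equilibrium'")
    model_is_fold = spec.model == "fold"
    burn_in = int(spec.burn_in_fraction * spec.n_steps)
    config = SimConfig(
        n_steps=spec.n_steps,
        dt=spec.dt,
        epsilon=spec.epsilon,
        x0=spec.x0,
        stop_on_escape=model_is_fold,
    )
    rows = []
    for alpha in spec.alphas:
        fixed = alpha if spec.fix_alpha else None
        for r in range(spec.n_replicates):
            noises = [
                make_noise_increments(
                    spec.n_steps, alpha, spec.gamma_N, spec.dt,
                    seed=(spec.master_seed, r, i),
                )
                for i in range(spec.trajectories_per_estimate)
            ]
            for k in spec.k_values:
                model = PotentialModel(spec.model, k)
                pooled = []
                stopped = False
                for noise in noises:
                    traj = tamed_euler_maruyama(model, k, config, noise)
                    if traj.truncated_at is not None:
                        stopped = True
                    pooled.append(
                        _thin_states(traj, burn_in, spec.points_per_trajectory)
                    )
                x = np.concatenate(pooled)
                theory = _theory_gamma(spec.model, k, alpha, spec.gamma_N)
                if len(x) >= 100 and np.ptp(x) > 0:
                    alpha_hat, gamma_hat = _fit(x, spec.fit_method, fixed)
                    var_hat = variance_estimator(x)
                    ac1_hat = lag1_autocorr(x)
                else:
                    alpha_hat = gamma_hat = var_hat = ac1_hat = math.nan
                rows.append(
                    {
                        "protocol": "equilibrium",
                        "model": spec.model,
                        "alpha": alpha,
                        "k": k,
                        "replicate": r,
                        "n_points": len(x),
                        "gamma_hat": gamma_hat,
                        "alpha_hat": alpha_hat,
                        "variance_hat": var_hat,
                        "ac1_hat": ac1_hat,
                        "theory_gamma_x": theory,
                        "relative_error": gamma_hat / theory - 1.0,
                        "stopped": stopped,
                    }
                )
    return pd.DataFrame(rows)


def run_nonequilibrium(spec: ExperimentSpec) -> pd.DataFrame:
    """Ramp protocol.  One row per (alpha, trajectory, anchor).

    Each trajectory equilibrates at k = ramp_start, then k decreases
    linearly toward the bifurcation; rolling-window indicators are evaluated
    on the ramp segment and the gamma_hat series is additionally smoothed
    (``gamma_smooth``).  Fold trajectories that escape contribute only their
    pre-escape anchors.
    """
    if spec.protocol != "nonequilibrium":
        raise ValueError(f"spec.protocol is {spec.protocol!r}, expected 'nonequilibrium'")
    ramp = k_ramp(spec.ramp_start, spec.ramp_end, spec.ramp_step)
    n_ramp = len(ramp)
    n_total = spec.equilibration_steps + n_ramp
    schedule = np.concatenate([np.full(spec.equilibration_steps, spec.ramp_start), ramp])
    model_is_fold = spec.model == "fold"
    config = SimConfig(
        n_steps=n_total,
        dt=spec.dt,
        epsilon=spec.epsilon,
        x0=spec.x0,
        stop_on_escape=model_is_fold,
    )
    rows = []
    for alpha in spec.alphas:
        fixed = alpha if spec.fix_alpha else None
        for i in range(spec.n_trajectories):
            noise = make_noise_increments(
                n_total, alpha, spec.gamma_N, spec.dt, seed=(spec.master_seed, i)
            )
            model = PotentialModel(spec.model, spec.ramp_start)
            traj = tamed_euler_maruyama(model, schedule, config, noise)
            try:
                sub = _slice_from(traj, spec.equilibration_steps)
                ews = rolling_ews(
                    sub,
                    window=spec.window,
                    stride=spec.stride,
                    fixed_alpha=fixed,
                    method=spec.fit_method,
                )
            except ValueError:
                continue  # escaped before a single full window
            gamma_smooth = smooth_series(ews.gamma_hat, spec.smooth_window)
            for a in range(len(ews)):
                k_a = ews.k[a]
                rows.append(
                    {
                        "protocol": "nonequilibrium",
                        "model": spec.model,
                        "alpha": alpha,
                        "trajectory": i,
                        "anchor_step": int(ews.anchor_index[a]),
                        "t": ews.time[a],
                        "k": k_a,
                        "gamma_hat": ews.gamma_hat[a],
                        "gamma_smooth": gamma_smooth[a],
                        "alpha_hat": ews.alpha_hat[a],
                        "variance_hat": ews.variance_hat[a],
                        "ac1_hat": ews.ac1_hat[a],
                        "theory_gamma_x": _theory_gamma(spec.model, k_a, alpha, spec.gamma_N),
                        "truncated": traj.truncated_at is not None,
                    }
                )
    return pd.DataFrame(rows)


def summarize_nonequilibrium(df: pd.DataFrame) -> pd.DataFrame:
    """Across-trajectory mean indicator series per (model, alpha, anchor)."""
    g = df.groupby(["model", "alpha", "anchor_step"], as_index=False)
    out = g.agg(
        t=("t", "first"),
        k=("k", "first"),
        gamma_hat=("gamma_hat", "mean"),
        gamma_smooth=("gamma_smooth", "mean"),
        alpha_hat=("alpha_hat", "mean"),
        variance_hat=("variance_hat", "mean"),
        theory_gamma_x=("theory_gamma_x", "first"),
        n_trajectories=("trajectory", "count"),
    )
    return out.sort_values(["model", "alpha", "anchor_step"], ignore_index=True)


def run_divergence_demo(spec: ExperimentSpec) -> pd.DataFrame:
    """Constant-k false-positive demonstration.  One row per
    (alpha, trajectory, anchor): expanding-window running variance and
    running gamma_hat on the post-equilibration segment of an OU path.
    """
    if spec.protocol != "divergence":
        raise ValueError(f"spec.protocol is {spec.protocol!r}, expected 'divergence'")
    k = spec.divergence_k
    n_total = spec.equilibration_steps + spec.divergence_steps
    config = SimConfig(n_steps=n_total, dt=spec.dt, epsilon=spec.epsilon, x0=spec.x0)
    model = PotentialModel("ou", k)
    rows = []
    for alpha in spec.divergence_alphas:
        fixed = alpha if spec.fix_alpha else None
        for i in range(spec.divergence_n_traj):
            noise = make_noise_increments(
                n_total, alpha, spec.gamma_N, spec.dt, seed=(spec.master_seed, i)
            )
            traj = tamed_euler_maruyama(model, k, config, noise)
            sub = _slice_from(traj, spec.equilibration_steps)
            ews = expanding_ews(
                sub, every=spec.divergence_every, fixed_alpha=fixed,
                method=spec.fit_method,
            )
            for a in range(len(ews)):
                rows.append(
                    {
                        "protocol": "divergence",
                        "model": "ou",
                        "alpha": alpha,
                        "k": k,
                        "trajectory": i,
                        "anchor_step": int(ews.anchor_index[a]),
                        "gamma_hat": ews.gamma_hat[a],
                        "alpha_hat": ews.alpha_hat[a],
                        "variance_hat": ews.variance_hat[a],
                    }
                )
    return pd.DataFrame(rows)


def _mid_to_final_change(series: np.ndarray) -> float:
    """|v_last - v_mid| / v_mid over the anchor sequence — the convergence
    diagnostic used for the divergence contrast."""
    mid = series[len(series) // 2]
    return abs(series[-1] - mid) / abs(mid)


def divergence_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Per-alpha stabilization statistics of the divergence demonstration.

    For each trajectory the relative mid-to-final change of the running
    variance and running gamma_hat is computed over the anchor sequence;
    reported are the fractions of trajectories with change < 10% ("stable")
    and > 50% ("divergent"), the mean final values, and the across-trajectory
    dispersion (IQR/median) of the final-anchor estimates.
    """
    out = []
    for alpha, g in df.groupby("alpha"):
        ch_v, ch_g, fin_v, fin_g = [], [], [], []
        for _, tg in g.groupby("trajectory"):
            tg = tg.sort_values("anchor_step")
            v = tg["variance_hat"].to_numpy()
            ga = tg["gamma_hat"].to_numpy()
            ch_v.append(_mid_to_final_change(v))
            ch_g.append(_mid_to_final_change(ga))
            fin_v.append(v[-1])
            fin_g.append(ga[-1])
        ch_v, ch_g = np.array(ch_v), np.array(ch_g)
        fin_v, fin_g = np.array(fin_v), np.array(fin_g)

        def _disp(x):
            q25, q50, q75 = np.percentile(x, [25, 50, 75])
            return (q75 - q25) / q50

        out.append(
            {
                "alpha": alpha,
                "n_trajectories": len(ch_v),
                "frac_var_stable": float(np.mean(ch_v < 0.10)),
                "frac_gamma_stable": float(np.mean(ch_g < 0.10)),
                "frac_var_divergent": float(np.mean(ch_v > 0.50)),
                "mean_final_variance": float(fin_v.mean()),
                "mean_final_gamma": float(fin_g.mean()),
                "dispersion_final_variance": _disp(fin_v),
                "dispersion_final_gamma": _disp(fin_g),
            }
        )
    return pd.DataFrame(out)
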