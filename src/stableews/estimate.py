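"""Estimation of SaS parameters and classical early-warning statistics.

The warning statistic is the fitted scale gamma_hat of the observed states.
Two fitters are provided:

* :func:`fit_sas_quantile` — McCulloch's quantile method (symmetric case).
  The tail-to-body quantile ratio nu = (q95 - q05)/(q75 - q25) is a strictly
  decreasing function of alpha and independent of scale; inverting it through
  a lookup table gives alpha_hat, and the interquartile range divided by the
  tabulated IQR of a unit-scale law gives gamma_hat.  The tables are built
  once from the exact stable quantiles (scipy) on an alpha grid 0.5..2.0 and
  interpolated linearly; alpha_hat is clipped to [0.6, 2], the range where
  the inversion is well conditioned.
* :func:`fit_sas_ecf` — regression of log(-log |ecf|) on log u, which is
  exactly linear with slope alpha and intercept alpha*log(gamma) for an SaS
  law; used as an independent cross-check of the quantile fitter.

Windowed series (:func:`rolling_ews`, :func:`expanding_ews`) evaluate the
fitters, the sample variance and the lag-1 autocorrelation along a
trajectory.  Rolling windows are trailing (causal) — an early-warning
statistic must not look into the future; the visual smoother
(:func:`smooth_series`) is centered because it is a presentation aid, not a
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .integrate import Trajectory

__all__ = [
    "EWSeries",
    "fit_sas_quantile",
    "fit_sas_ecf",
    "variance_estimator",
    "lag1_autocorr",
    "rolling_ews",
    "expanding_ews",
    "smooth_series",
]

ALPHA_MIN, ALPHA_MAX = 0.6, 2.0
_MIN_FIT_SAMPLES = 100


@lru_cache(maxsize=1)
def _mcculloch_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(alpha grid, nu(alpha), IQR(alpha)) for the symmetric stable family,
    from exact quantiles.  nu is strictly decreasing in alpha."""
    grid = np.round(np.arange(0.50, 2.0001, 0.05), 4)
    q75 = np.array([_sstats.levy_stable.ppf(0.75, a, 0.0) for a in grid])
    q95 = np.array([_sstats.levy_stable.ppf(0.95, a, 0.0) for a in grid])
    return grid, q95 / q75, 2.0 * q75


def _check_samples(samples) -> np.ndarray:
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if len(x) < _MIN_FIT_SAMPLES:
        raise ValueError(f"need at least {_MIN_FIT_SAMPLES} samples, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples contain non-finite values")
    return x


def fit_sas_quantile(
    samples, fixed_alpha: float | None = None
) -> tuple[float, float]:
    """McCulloch quantile fit of a symmetric stable law.

    Returns ``(alpha_hat, gamma_hat)``.  With ``fixed_alpha`` given only the
    scale is estimated (alpha_hat echoes the fixed value).  Quantiles use
    linear interpolation between order statistics.
    """
    x = _check_samples(samples)
    q05, q25, q75, q95 = np.percentile(x, [5.0, 25.0, 75.0, 95.0])
    iqr = q75 - q25
    if iqr <= 0.0:
        raise ValueError("degenerate data: zero interquartile range")
    grid, nu_tab, iqr_tab = _mcculloch_tables()
    if fixed_alpha is not None:
        if not ALPHA_MIN <= fixed_alpha <= ALPHA_MAX:
            raise ValueError(f"fixed_alpha must be in [{ALPHA_MIN}, {ALPHA_MAX}]")
        alpha_hat = float(fixed_alpha)
    else:
        nu_hat = (q95 - q05) / iqr
        # nu decreasing in alpha: interpolate on the reversed table
        alpha_hat = float(np.interp(nu_hat, nu_tab[::-1], grid[::-1]))
        alpha_hat = min(max(alpha_hat, ALPHA_MIN), ALPHA_MAX)
    gamma_hat = float(iqr / np.interp(alpha_hat, grid, iqr_tab))
    return alpha_hat, gamma_hat


def _default_u_grid(x: np.ndarray) -> np.ndarray:
    """Frequencies spanning the informative band |ecf| in ~(0.1, 0.9),
    anchored on a robust scale guess from the interquartile range."""
    q25, q75 = np.percentile(x, [25.0, 75.0])
    scale = (q75 - q25) / 2.0
    if scale <= 0.0:
        raise ValueError("degenerate data: zero interquartile range")
    return np.geomspace(0.25, 1.6, 8) / scale


def fit_sas_ecf(
    samples, u_grid=None, fixed_alpha: float | None = None
) -> tuple[float, float]:
    """Empirical-characteristic-function regression fit.

    For an SaS law, -log phi(u) = (gamma u)**alpha, so log(-log phi) is
    linear in log u with slope alpha and intercept alpha log gamma.  Only
    frequencies where the empirical |phi| lies in (0.05, 0.95) enter the
    regression; fewer than two such points raises (ill-conditioned grid).
    """
    x = _check_samples(samples)
    u = _default_u_grid(x) if u_grid is None else np.asarray(u_grid, dtype=float)
    if np.any(u <= 0):
        raise ValueError("u_grid must be strictly positive")
    phi = np.array([np.mean(np.cos(ui * x)) for ui in u])
    keep = (phi > 0.05) & (phi < 0.95)
    if keep.sum() < 2:
        raise ValueError("ill-conditioned u_grid: fewer than 2 usable frequencies")
    lu = np.log(u[keep])
    y = np.log(-np.log(phi[keep]))
    if fixed_alpha is not None:
        alpha_hat = float(fixed_alpha)
        log_gamma = float(np.mean(y - alpha_hat * lu) / alpha_hat)
    else:
        slope, intercept = np.polyfit(lu, y, 1)
        alpha_hat = float(min(max(slope, ALPHA_MIN), ALPHA_MAX))
        log_gamma = float(intercept / slope)
    return alpha_hat, float(np.exp(log_gamma))


def variance_estimator(samples) -> float:
    """Unbiased sample variance."""
    x = np.asarray(samples, dtype=float)
    if len(x) < 2:
        raise ValueError("variance needs at least 2 samples")
    return float(np.var(x, ddof=1))


def lag1_autocorr(samples) -> float:
    """Lag-1 Pearson autocorrelation corr(x[:-1], x[1:])."""
    x = np.asarray(samples, dtype=float)
    if len(x) < 3:
        raise ValueError("lag-1 autocorrelation needs at least 3 samples")
    a, b = x[:-1], x[1:]
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        raise ValueError("degenerate data: constant series")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


@dataclass
class EWSeries:
    """Early-warning indicators evaluated along a trajectory."""

    anchor_index: np.ndarray
    time: np.ndarray
    k: np.ndarray
    gamma_hat: np.ndarray
    alpha_hat: np.ndarray
    variance_hat: np.ndarray
    ac1_hat: np.ndarray
    window: int
    stride: int
    method: str = "quantile"

    def __len__(self) -> int:
        return len(self.anchor_index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "anchor_step": self.anchor_index,
                "t": self.time,
                "k": self.k,
                "gamma_hat": self.gamma_hat,
                "alpha_hat": self.alpha_hat,
                "variance_hat": self.variance_hat,
                "ac1_hat": self.ac1_hat,
            }
        )


def _fit(x: np.ndarray, method: str, fixed_alpha: float | None):
    if method == "quantile":
        return fit_sas_quantile(x, fixed_alpha=fixed_alpha)
    if method == "ecf":
        return fit_sas_ecf(x, fixed_alpha=fixed_alpha)
    raise ValueError(f"unknown fit method {method!r}")


def _ew_at_anchors(
    traj: Trajectory, anchors, window_of, method: str, fixed_alpha, window, stride
) -> EWSeries:
    g, a, v, c, t, kk = [], [], [], [], [], []
    kept = []
    for j in anchors:
        x = window_of(j)
        alpha_hat, gamma_hat = _fit(x, method, fixed_alpha)
        g.append(gamma_hat)
        a.append(alpha_hat)
        v.append(variance_estimator(x))
        c.append(lag1_autocorr(x))
        t.append(traj.times[j])
        kk.append(traj.k_schedule[j - 1])
        kept.append(j)
    return EWSeries(
        anchor_index=np.array(kept, dtype=int),
        time=np.array(t),
        k=np.array(kk),
        gamma_hat=np.array(g),
        alpha_hat=np.array(a),
        variance_hat=np.array(v),
        ac1_hat=np.array(c),
        window=window,
        stride=stride,
        method=method,
    )


def rolling_ews(
    traj: Trajectory,
    window: int = 300,
    stride: int = 150,
    fixed_alpha: float | None = None,
    method: str = "quantile",
) -> EWSeries:
    """Trailing-window indicators every ``stride`` steps.

    Anchor j uses the raw states X_{j-window+1}..X_j; anchors run from
    ``window`` to the last valid step.  Estimates are causal: nothing after
    the anchor enters the window.
    """
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be positive")
    n = traj.n_valid_steps
    if n < window:
        raise ValueError(f"trajectory has {n} valid steps, window is {window}")
    anchors = range(window, n + 1, stride)
    return _ew_at_anchors(
        traj,
        anchors,
        lambda j: traj.values[j - window + 1 : j + 1],
        method,
        fixed_alpha,
        window,
        stride,
    )


def expanding_ews(
    traj: Trajectory,
    every: int = 300,
    fixed_alpha: float | None = None,
    method: str = "quantile",
) -> EWSeries:
    """Running (expanding-prefix) indicators at anchors every, 2*every, ...

    Anchor j uses all states X_1..X_j.  The running variance converges for
    alpha = 2 but keeps jumping for alpha < 2 (no second moment); the running
    gamma_hat converges for every alpha.
    """
    if every < 1:
        raise ValueError("every must be positive")
    n = traj.n_valid_steps
    if n < every:
        raise ValueError(f"trajectory has {n} valid steps, anchor spacing is {every}")
    anchors = range(every, n + 1, every)
    return _ew_at_anchors(
        traj,
        anchors,
        lambda j: traj.values[1 : j + 1],
        method,
        fixed_alpha,
        every,
        every,
    )


def smooth_series(values, window: int = 100) -> np.ndarray:
    """Centered moving average with symmetric shrinkage at the edges.

    Output has the same length as the input; window = 1 is the identity.
    The effective half-width at index i is min(i, n-1-i, window//2).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(values, dtype=float)
    n = len(x)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        h = min(i, n - 1 - i, half)
        out[i] = x[i - h : i + h + 1].mean()
    return out
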