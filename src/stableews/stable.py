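"""Symmetric alpha-stable (SaS) distributions.

The symmetric centered stable law SaS(gamma) with characteristic exponent
``alpha`` in (0, 2] and scale ``gamma >= 0`` has characteristic function

    E exp(i u Z) = exp(-gamma**alpha * |u|**alpha).

Two members have closed-form densities: alpha = 2 is Gaussian with variance
``2 * gamma**2`` (note: *not* gamma**2 — the scale convention above puts a
factor 2 into the Gaussian variance), and alpha = 1 is Cauchy with half-width
gamma.  For alpha < 2 absolute moments of order >= alpha diverge, which is
the mathematical root of the failure of variance-based early-warning
statistics under heavy-tailed forcing.

Sampling uses the Chambers–Mallows–Stuck (CMS) transform of a uniform angle
U on (-pi/2, pi/2) and an independent unit exponential W.  The base draws
(U, W) depend only on the seed, never on alpha, so two samples generated
with the same seed but different alpha experience their extreme base events
at the same indices — the cross-alpha coupling used by the simulation
protocols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StableParams",
    "sas_characteristic_function",
    "sas_pdf_closed_form",
    "sas_sample",
    "abs_moment_exists",
    "empirical_abs_moment",
]


@dataclass(frozen=True)
class StableParams:
    """Parameters of a symmetric centered stable law.

    Only the symmetric centered family is supported: ``beta`` (skewness) and
    ``delta`` (location) must be zero.
    """

    alpha: float
    gamma: float
    beta: float = 0.0
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 2.0:
            raise ValueError(f"alpha must be in (0, 2], got {self.alpha}")
        if self.gamma < 0.0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.beta != 0.0:
            raise ValueError("only symmetric laws supported (beta must be 0)")
        if self.delta != 0.0:
            raise ValueError("only centered laws supported (delta must be 0)")

    @property
    def is_gaussian(self) -> bool:
        return self.alpha == 2.0

    @property
    def gaussian_variance(self) -> float:
        """Variance in the Gaussian case, 2*gamma**2."""
        if not self.is_gaussian:
            raise ValueError("variance is only defined for alpha = 2")
        return 2.0 * self.gamma**2


def sas_characteristic_function(u, params: StableParams):
    """exp(-gamma**alpha * |u|**alpha); real, symmetric in u, equals 1 at 0."""
    u = np.asarray(u, dtype=float)
    out = np.exp(-(params.gamma**params.alpha) * np.abs(u) ** params.alpha)
    return out if out.ndim else float(out)


def sas_pdf_closed_form(x, params: StableParams):
    """Closed-form density; only the Gaussian (alpha=2) and Cauchy (alpha=1)
    members have one.  Other alphas raise ValueError — general stable
    densities require numeric Fourier inversion of the characteristic
    function and are deliberately not part of the public API.
    """
    if params.gamma <= 0.0:
        raise ValueError("closed-form density requires gamma > 0")
    x = np.asarray(x, dtype=float)
    g = params.gamma
    if params.alpha == 2.0:
        out = np.exp(-(x**2) / (4.0 * g**2)) / (2.0 * g * math.sqrt(math.pi))
    elif params.alpha == 1.0:
        out = g / (math.pi * (g**2 + x**2))
    else:
        raise ValueError(
            f"no closed-form density for alpha={params.alpha}; only alpha in {{1, 2}}"
        )
    return out if out.ndim else float(out)


def _cms_base_draws(n: int, seed) -> tuple[np.ndarray, np.ndarray]:
    """Seed-determined base draws shared by every alpha: a uniform angle on
    (-pi/2, pi/2) drawn first, then a unit exponential."""
    rng = np.random.default_rng(seed)
    u = rng.uniform(-math.pi / 2.0, math.pi / 2.0, size=n)
    w = rng.exponential(1.0, size=n)
    return u, w


def sas_sample(n: int, params: StableParams, seed) -> np.ndarray:
    """Draw ``n`` i.i.d. SaS(gamma) variates via the CMS transform.

    ``seed`` may be an int or a tuple of ints (fed to
    ``numpy.random.default_rng``).  Identical seeds yield identical base
    draws for every alpha.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    u, w = _cms_base_draws(n, seed)
    a = params.alpha
    if a == 2.0:
        # CMS at alpha=2 reduces to 2 sin(U) sqrt(W): N(0, 2) for gamma=1
        z = 2.0 * np.sin(u) * np.sqrt(w)
    elif a == 1.0:
        z = np.tan(u)
    else:
        z = (
            np.sin(a * u)
            / np.cos(u) ** (1.0 / a)
            * (np.cos((1.0 - a) * u) / w) ** ((1.0 - a) / a)
        )
    return params.gamma * z


def abs_moment_exists(alpha: float, eta: float) -> bool:
    """Whether E|Z|**eta is finite: all moments exist at alpha=2; otherwise
    only orders eta < alpha."""
    if not 0.0 < alpha <= 2.0:
        raise ValueError(f"alpha must be in (0, 2], got {alpha}")
    if eta <= 0.0:
        raise ValueError(f"moment order eta must be > 0, got {eta}")
    return alpha == 2.0 or eta < alpha


def empirical_abs_moment(samples, eta: float) -> float:
    """Mean of |x|**eta over the sample."""
    if eta <= 0.0:
        raise ValueError("eta must be > 0")
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("samples must be non-empty")
    return float(np.mean(np.abs(x) ** eta))
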