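"""The two model systems and the closed-form scale-parameter theory.

Models (drift = -U'(x, k)):

* ``ou``   — linear Ornstein–Uhlenbeck: U = k x²/2, drift -k x; bifurcation
  at k = 0 (stable fixed point x* = 0 for k > 0).
* ``fold`` — saddle-node normal form: U = x³/3 - k x, drift k - x²; for
  k > 0 a stable fixed point at +sqrt(k) and an unstable one at -sqrt(k)
  that collide at k = 0.

Linearizing the fold model around +sqrt(k) yields an OU process with
effective rate kappa = 2 sqrt(k), so every OU result applies locally to the
fold model with k -> kappa.

Theory for OU driven by SaS noise of scale gamma_N (x0 = 0 convention):
the response X(t) is itself SaS with scale

    gamma_X(t) = gamma_N * ((1 - exp(-alpha k t)) / (alpha k))**(1/alpha)
    gamma_X    = gamma_N * (1 / (alpha k))**(1/alpha)        (t -> inf)

gamma_X diverges as k -> 0+, for every alpha — this monotone inflation is
the early-warning indicator.  At alpha = 2 it reduces to the classical
variance scaling: Var X = 2 gamma_X² = gamma_N²/k.

Note on the Gaussian variance prefactor: with driving increments
N(t)-N(s) ~ N(0, 2 gamma_N² (t-s)) (the SaS scale convention), the OU
variance is Var X(t) = (gamma_N²/k)(1 - exp(-2kt)).  This is the unique form
consistent with the stationary Fokker–Planck balance and with
Var = 2 gamma_X(t)²; ``ou_variance`` implements it exactly so that
sqrt(ou_variance(inf)/2) == gamma_x_limit at alpha = 2 holds to machine
precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "PotentialModel",
    "FixedPoint",
    "fold_fixed_points",
    "linearized_rate",
    "variance_is_finite",
    "ou_variance",
    "gamma_x_t",
    "gamma_x_limit",
]

_TAIL_EXPONENT = {"ou": 2, "fold": 3}


@dataclass(frozen=True)
class PotentialModel:
    """A named potential U(x, k) with its bifurcation parameter."""

    name: str
    k: float

    def __post_init__(self) -> None:
        if self.name not in _TAIL_EXPONENT:
            raise ValueError(f"unknown model {self.name!r}; use 'ou' or 'fold'")

    @property
    def tail_exponent_c(self) -> int:
        """Growth order of U at infinity: 2 for ou, 3 for fold."""
        return _TAIL_EXPONENT[self.name]

    def potential(self, x: float, k: float | None = None) -> float:
        k = self.k if k is None else k
        if self.name == "ou":
            return 0.5 * k * x * x
        return x**3 / 3.0 - k * x

    def potential_prime(self, x: float, k: float | None = None) -> float:
        k = self.k if k is None else k
        if self.name == "ou":
            return k * x
        return x * x - k

    def drift(self, x: float, k: float | None = None) -> float:
        """-U'(x, k)."""
        return -self.potential_prime(x, k)

    @classmethod
    def ou(cls, k: float) -> "PotentialModel":
        return cls("ou", k)

    @classmethod
    def fold(cls, k: float) -> "PotentialModel":
        return cls("fold", k)


class FixedPoint(NamedTuple):
    x: float
    stability: str  # "stable" | "unstable" | "degenerate"


def fold_fixed_points(k: float) -> tuple[FixedPoint, ...]:
    """Fixed points of dX = (k - X²) dt: +sqrt(k) stable and -sqrt(k)
    unstable for k > 0, a single degenerate root at k = 0, none for k < 0."""
    if k > 0:
        r = math.sqrt(k)
        return (FixedPoint(r, "stable"), FixedPoint(-r, "unstable"))
    if k == 0:
        return (FixedPoint(0.0, "degenerate"),)
    return ()


def linearized_rate(k: float) -> float:
    """Effective OU rate kappa = 2 sqrt(k) of the fold model near +sqrt(k)."""
    if k <= 0:
        raise ValueError(f"linearized rate requires k > 0, got {k}")
    return 2.0 * math.sqrt(k)


def variance_is_finite(tail_exponent_c: float, alpha: float) -> bool:
    """Finite-variance criterion for a confining potential of growth order c
    driven by SaS(alpha) noise: finite iff alpha == 2 or c > 4 - alpha."""
    if tail_exponent_c not in (2, 3, 4):
        raise ValueError(f"supported tail exponents are 2, 3, 4; got {tail_exponent_c}")
    if not 0.0 < alpha <= 2.0:
        raise ValueError(f"alpha must be in (0, 2], got {alpha}")
    return alpha == 2.0 or tail_exponent_c > 4.0 - alpha


def ou_variance(t, k: float, gamma_N: float):
    """Variance of the Gaussian (alpha = 2) OU response started at x0 = 0:

        Var X(t) = (gamma_N²/k) (1 - exp(-2 k t)),  limit gamma_N²/k.

    ``t`` may be ``math.inf`` for the stationary limit, or an array.
    """
    if k <= 0:
        raise ValueError(f"ou_variance requires k > 0, got {k}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = (gamma_N**2 / k) * -np.expm1(-2.0 * k * t)
    return out if out.ndim else float(out)


def _growth_factor(t: np.ndarray, rate: np.ndarray) -> np.ndarray:
    """(1 - exp(-rate*t)) / rate, with the analytic rate->0 limit t."""
    rate = np.asarray(rate, dtype=float)
    small = rate * t < 1e-12
    safe = np.where(small, 1.0, rate)
    return np.where(small, t * (1.0 - rate * t / 2.0), -np.expm1(-safe * t) / safe)


def gamma_x_t(t, k: float, alpha: float, gamma_N: float):
    """Transient scale of the OU response (x0 = 0):

        gamma_X(t) = gamma_N ((1 - exp(-alpha k t)) / (alpha k))**(1/alpha)

    Continuous at k = 0, where it equals gamma_N * t**(1/alpha).
    Non-decreasing in t; converges to :func:`gamma_x_limit` for k > 0.
    """
    if k < 0:
        raise ValueError(f"gamma_x_t requires k >= 0, got {k}")
    if not 0.0 < alpha <= 2.0:
        raise ValueError(f"alpha must be in (0, 2], got {alpha}")
    if gamma_N < 0:
        raise ValueError("gamma_N must be >= 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = gamma_N * _growth_factor(t, alpha * k) ** (1.0 / alpha)
    return out if out.ndim else float(out)


def gamma_x_limit(k: float, alpha: float, gamma_N: float) -> float:
    """Stationary scale gamma_X = gamma_N (1/(alpha k))**(1/alpha).

    Strictly increasing as k decreases — the early-warning signal.  Diverges
    at the bifurcation, so k <= 0 raises.
    """
    if k <= 0:
        raise ValueError(f"gamma_x_limit requires k > 0, got {k}")
    if not 0.0 < alpha <= 2.0:
        raise ValueError(f"alpha must be in (0, 2], got {alpha}")
    if gamma_N < 0:
        raise ValueError("gamma_N must be >= 0")
    return gamma_N * (1.0 / (alpha * k)) ** (1.0 / alpha)
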