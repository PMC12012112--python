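"""Path simulation: scaled SaS noise increments, plain and tamed
Euler–Maruyama schemes, the basin-escape stopping rule and parameter ramps.

Over a step of length dt the driving noise contributes an SaS variate of
scale gamma_N * dt**(1/alpha); increments are pre-generated so that a stored
:class:`NoiseSequence` can be replayed identically against different drifts
(the equilibrium protocol reuses one sequence across the whole k-grid).

The plain Euler–Maruyama update

    x_j = x_{j-1} - U'(x_{j-1}, k_j) dt + dN_j

is unstable for superlinear drifts: one large Levy jump can put the state
where |U'| dt overshoots, after which the iteration blows up in a few steps.
The tamed variant divides the drift by (1 + eps |U'|), bounding the drift
term by dt/eps per step while perturbing it only at O(eps |U'|²) — for
eps << dt the two schemes are indistinguishable on well-behaved paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import PotentialModel
from .stable import StableParams, sas_sample

__all__ = [
    "SimConfig",
    "NoiseSequence",
    "Trajectory",
    "make_noise_increments",
    "tamed_euler_maruyama",
    "plain_euler_maruyama",
    "escape_stop",
    "k_ramp",
]

_DEFAULT_DT = 0.004


@dataclass(frozen=True)
class SimConfig:
    """Discretization settings.  Defaults follow the study protocol:
    dt = 0.004, x0 = 0.5, taming constant eps = dt/100."""

    n_steps: int
    dt: float = _DEFAULT_DT
    epsilon: float | None = None
    x0: float = 0.5
    seed: object = None
    stop_on_escape: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.epsilon is None:
            object.__setattr__(self, "epsilon", self.dt / 100.0)
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass(frozen=True)
class NoiseSequence:
    """Pre-generated noise increments, already scaled by dt**(1/alpha)."""

    increments: np.ndarray
    alpha: float
    gamma_N: float
    dt: float
    seed: object = None

    def __len__(self) -> int:
        return len(self.increments)


def make_noise_increments(
    n: int, alpha: float, gamma_N: float, dt: float, seed
) -> NoiseSequence:
    """n i.i.d. increments dt**(1/alpha) * N_j with N_j ~ SaS(gamma_N).

    The sum of any m consecutive increments is SaS(gamma_N * (m dt)**(1/alpha))
    in law — the white-noise scaling of the driving process.  Base draws are
    shared across alpha for a fixed seed (see :func:`stableews.sas_sample`).
    """
    params = StableParams(alpha=alpha, gamma=gamma_N)
    inc = dt ** (1.0 / alpha) * sas_sample(n, params, seed)
    return NoiseSequence(increments=inc, alpha=alpha, gamma_N=gamma_N, dt=dt, seed=seed)


@dataclass
class Trajectory:
    """A simulated path on the uniform grid t_j = j*dt, j = 0..n_steps.

    ``values[0]`` is the initial state.  If the escape rule fired,
    ``truncated_at`` holds the first step index past the basin boundary and
    later values are NaN; if the (plain) scheme produced a non-finite state,
    ``diverged_at`` holds that index.
    """

    times: np.ndarray
    values: np.ndarray
    k_schedule: np.ndarray
    dt: float
    model_name: str
    alpha: float
    gamma_N: float
    scheme: str
    x0: float
    epsilon: float
    seed: object = None
    truncated_at: int | None = None
    diverged_at: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return len(self.values) - 1

    @property
    def n_valid_steps(self) -> int:
        """Number of steps with a usable state (escape truncation keeps the
        crossing step itself out; divergence invalidates from that index)."""
        if self.truncated_at is not None:
            return self.truncated_at - 1
        if self.diverged_at is not None:
            return self.diverged_at - 1
        return self.n_steps

    def states(self) -> np.ndarray:
        """Post-initial valid states X_1..X_m (m = n_valid_steps)."""
        return self.values[1 : self.n_valid_steps + 1]


def escape_stop(x_next: float, k: float) -> bool:
    """Basin-escape rule for the fold model: stop once the state falls below
    -sqrt(k) - k/10, i.e. clearly past the unstable fixed point."""
    if k < 0:
        raise ValueError("escape rule is defined for k >= 0")
    return x_next < -math.sqrt(k) - k / 10.0


def k_ramp(k_start: float, k_end: float, step: float) -> np.ndarray:
    """Arithmetic ramp from k_start toward k_end, one value per integration
    step, excluding k_end itself: length ceil((k_start-k_end)/step).

    k_ramp(5, 0, 1e-4) has 50 000 entries, first 5.0 and last 1e-4 — the ramp
    stops one step short of the bifurcation value.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if k_start == k_end:
        raise ValueError("degenerate ramp: k_start == k_end")
    if k_start < k_end:
        raise ValueError("ramp must decrease: k_start > k_end required")
    n = math.ceil((k_start - k_end) / step - 1e-12)
    return k_start - step * np.arange(n)


def _as_schedule(k_schedule, n_steps: int) -> np.ndarray:
    ks = np.asarray(k_schedule, dtype=float)
    if ks.ndim == 0:
        return np.full(n_steps, float(ks))
    if len(ks) < n_steps:
        raise ValueError(f"k_schedule has {len(ks)} entries for {n_steps} steps")
    return ks[:n_steps]


def _integrate(
    model: PotentialModel,
    k_schedule,
    config: SimConfig,
    noise: NoiseSequence,
    tamed: bool,
) -> Trajectory:
    n = config.n_steps
    if len(noise) < n:
        raise ValueError(f"noise sequence has {len(noise)} increments, need {n}")
    if not math.isclose(noise.dt, config.dt):
        raise ValueError(f"noise dt {noise.dt} does not match config dt {config.dt}")
    ks = _as_schedule(k_schedule, n)
    inc = noise.increments
    dt = config.dt
    eps = config.epsilon
    is_fold = model.name == "fold"
    stop = config.stop_on_escape and is_fold

    values = np.empty(n + 1)
    values[0] = x = float(config.x0)
    truncated_at = None
    diverged_at = None
    for j in range(1, n + 1):
        kj = ks[j - 1]
        up = (x * x - kj) if is_fold else (kj * x)  # U'(x, k)
        if tamed:
            up = up / (1.0 + eps * abs(up))
        x = x - up * dt + inc[j - 1]
        if not (-1e150 < x < 1e150):  # also catches NaN
            diverged_at = j
            values[j:] = np.nan
            break
        values[j] = x
        if stop and x < -math.sqrt(kj) - kj / 10.0:
            truncated_at = j
            values[j + 1 :] = np.nan
            break

    return Trajectory(
        times=np.arange(n + 1) * dt,
        values=values,
        k_schedule=ks,
        dt=dt,
        model_name=model.name,
        alpha=noise.alpha,
        gamma_N=noise.gamma_N,
        scheme="tamed" if tamed else "plain",
        x0=config.x0,
        epsilon=eps,
        seed=config.seed if config.seed is not None else noise.seed,
        truncated_at=truncated_at,
        diverged_at=diverged_at,
    )


def tamed_euler_maruyama(
    model: PotentialModel, k_schedule, config: SimConfig, noise: NoiseSequence
) -> Trajectory:
    """Tamed Euler–Maruyama: drift U'/(1 + eps|U'|), stable under the large
    jumps of heavy-tailed noise (the tamed drift term never exceeds dt/eps)."""
    traj = _integrate(model, k_schedule, config, noise, tamed=True)
    if traj.diverged_at is not None:
        raise AssertionError("tamed scheme produced a non-finite state")
    return traj


def plain_euler_maruyama(
    model: PotentialModel, k_schedule, config: SimConfig, noise: NoiseSequence
) -> Trajectory:
    """Reference (untamed) scheme.  Divergence is reported via
    ``Trajectory.diverged_at``, not raised."""
    return _integrate(model, k_schedule, config, noise, tamed=False)
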