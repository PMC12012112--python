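# stableews

Early-warning signals for tipping points in systems driven by symmetric
α-stable (heavy-tailed) noise.

## The problem

Nonlinear systems — ecosystems, climate elements, populations — can tip:
cross a bifurcation and shift abruptly to another state. The standard
statistical early-warning signs, rising variance and rising lag-1
autocorrelation, rest on linearizing the system near its stable state and
assuming Gaussian forcing. Many environmental records are instead
heavy-tailed, and a symmetric α-stable law SαS(γ) with tail index
α ∈ (0, 2) has **no finite variance**: the running sample variance of such a
series never converges and keeps jumping upward with sample size. A
variance-based monitor can therefore raise a "warning" while nothing in the
system moves toward a bifurcation — a false positive built into the
statistic, not the data.

## The indicator

For the linear (Ornstein–Uhlenbeck-type) system

    dX = −k X dt + dN^(α),     E e^{iuN(t)} = exp(−γ_N^α t |u|^α),

the response X(t) is itself SαS with scale

    γ_X(t) = γ_N ((1 − e^{−αkt})/(αk))^{1/α}  →  γ_X = γ_N (1/(αk))^{1/α}.

γ_X is finite for **every** α ∈ (0, 2], and grows monotonically as the
recovery rate k decreases toward the bifurcation at k = 0 — so the fitted
scale parameter γ̂_X of the observed states is a heavy-tail-safe
early-warning indicator. At α = 2 it reduces to the classical variance
scaling (Var X = 2γ_X² = γ_N²/k). Near the stable state +√k of the fold
(saddle-node) normal form dX = (k − X²) dt + dN, the same formulas apply
with the linearized rate κ = 2√k.

The package provides:

- `stable` — SαS parameterization, characteristic function, Gaussian/Cauchy
  closed forms, Chambers–Mallows–Stuck sampling with seed-shared base draws
  across α, moment-existence logic;
- `dynamics` — the OU and fold models, fixed points, linearization, the
  γ_X(t) and γ_X theory, the finite-variance criterion (finite iff α = 2 or
  the potential grows faster than |x|^{4−α});
- `integrate` — scaled noise increments, plain and *tamed* Euler–Maruyama
  schemes (drift U′/(1 + ε|U′|), stable under Lévy jumps), basin-escape
  stopping, parameter ramps;
- `estimate` — McCulloch quantile and characteristic-function-regression
  fitters, variance/autocorrelation, rolling and expanding indicator series;
- `experiments` — three seeded protocols (equilibrium grid, ramp toward the
  bifurcation, constant-k divergence demonstration) returning tidy tables;
- a thin `stableews` CLI (`simulate | fit | theory | equilibrium |
  nonequilibrium | divergence`).

## Worked example

```sh
python examples/simulate_and_fit.py
```

```
driving noise:    alpha = 1.5, gamma_N = 0.1, k = 1.0
fitted from path: alpha_hat = 1.463, gamma_hat = 0.06953
theory gamma_X  = 0.07631   (relative error -8.9%)
```

A stationary OU path (50 000 steps, Δt = 0.004) driven by SαS(α=1.5,
γ_N=0.1) noise is fitted by the quantile method after burn-in: the fitted
tail index recovers the driving α and the fitted scale matches
γ_N (1/(αk))^{1/α} — the quantity whose rise signals a shrinking k. The
other scripts in `examples/` demonstrate the sampler (`stable_sampling.py`),
the theory table (`theory_curves.py`), the false-positive variance contrast
(`false_positive_variance.py`) and the ramp protocol with the rising warning
signal (`ramp_warning_signal.py`).

CLI equivalents:

```sh
stableews theory --alpha 1.5 --k 1 --gamma-n 0.1
stableews simulate --model ou --alpha 1.5 --k 1 --steps 50000 --seed 101 --out-dir runs/
stableews fit runs/trajectory_ou_alpha1.5_seed101.csv --window 40000
stableews divergence --seed 4 --trajectories 25 --out-dir runs/divergence
```

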