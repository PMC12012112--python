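"""Simulate a stationary Ornstein–Uhlenbeck path under heavy-tailed noise and
recover the theoretical scale gamma_X from the states.

Integrates dX = -kX dt + dN (tamed Euler–Maruyama, dt = 0.004) for alpha=1.5,
discards a burn-in, and fits the stable scale by the McCulloch quantile
method — the measurement a practitioner would make on observed data.
"""

from stableews import (
    PotentialModel,
    SimConfig,
    fit_sas_quantile,
    gamma_x_limit,
    make_noise_increments,
    tamed_euler_maruyama,
)

alpha, k, gamma_N, n = 1.5, 1.0, 0.1, 50_000

config = SimConfig(n_steps=n, x0=0.5)
noise = make_noise_increments(n, alpha, gamma_N, config.dt, seed=101)
traj = tamed_euler_maruyama(PotentialModel.ou(k), k, config, noise)

alpha_hat, gamma_hat = fit_sas_quantile(traj.values[n // 5 :])
theory = gamma_x_limit(k, alpha, gamma_N)

print(f"driving noise:    alpha = {alpha}, gamma_N = {gamma_N}, k = {k}")
print(f"fitted from path: alpha_hat = {alpha_hat:.3f}, gamma_hat = {gamma_hat:.5f}")
print(f"theory gamma_X  = {theory:.5f}   (relative error {gamma_hat / theory - 1:+.1%})")
print(
    "\nThe fitted scale of the observed states matches\n"
    "gamma_N * (1/(alpha k))^(1/alpha): monitoring gamma_hat tracks the\n"
    "system's distance from the bifurcation."
)
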