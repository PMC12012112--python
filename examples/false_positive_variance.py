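"""Why rising variance is a false-positive risk under heavy-tailed noise.

Runs the expanding-window demonstration at constant k = 1 (nothing
approaches a bifurcation): for Gaussian noise the running variance settles,
but for alpha = 1.3 it keeps jumping upward — which a variance-based monitor
would misread as an early-warning sign.  The fitted stable scale gamma_hat
settles for both.
"""

import math

from stableews import ExperimentSpec, divergence_summary, ou_variance, run_divergence_demo

spec = ExperimentSpec(
    protocol="divergence",
    divergence_alphas=(2.0, 1.3),
    divergence_n_traj=25,  # reduced for a quick demo; the study uses 100
    master_seed=3,
)
summary = divergence_summary(run_divergence_demo(spec)).set_index("alpha")

print("alpha  frac var >50% change  mean final variance  final-gamma dispersion")
for alpha in (2.0, 1.3):
    s = summary.loc[alpha]
    print(
        f"{alpha:4.1f}   {s.frac_var_divergent:19.2f}  {s.mean_final_variance:18.4f}"
        f"  {s.dispersion_final_gamma:21.3f}"
    )

print(
    f"\nGaussian theory: Var X = gamma_N^2/k = {ou_variance(math.inf, 1.0, 0.1):.4f}.\n"
    "At alpha=2 the running variance ends near that value; at alpha=1.3 a\n"
    "sizable fraction of paths shows a >50% late jump in running variance at\n"
    "CONSTANT k — a spurious warning.  The fitted scale stays comparatively\n"
    "tight (low dispersion), making it the reliable indicator."
)
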