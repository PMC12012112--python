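"""The warning signal in action: ramp a fold system toward its tipping point.

Equilibrates dX = (k - X^2) dt + dN at k = 5, then lowers k linearly toward
the fold bifurcation at k = 0 while estimating the stable scale gamma_hat in
rolling 300-point windows every 150 steps (smoothed over 100 anchors).  The
indicator rises as the tipping point nears, for heavy-tailed noise included.
"""

from stableews import ExperimentSpec, run_nonequilibrium, summarize_nonequilibrium

spec = ExperimentSpec(
    protocol="nonequilibrium",
    model="fold",
    alphas=(1.5,),
    n_trajectories=5,  # reduced for a quick demo; the study uses 15
    master_seed=2,
)
mean = summarize_nonequilibrium(run_nonequilibrium(spec)).sort_values("anchor_step")

print("      k    mean smoothed gamma_hat   theory gamma_X (linearized)")
for _, row in mean.iloc[:: len(mean) // 8].iterrows():
    print(f"{row.k:8.3f}   {row.gamma_smooth:20.4f}   {row.theory_gamma_x:20.4f}")

tenth = max(1, len(mean) // 10)
lo = mean["gamma_smooth"].head(tenth).mean()
hi = mean["gamma_smooth"].tail(tenth).mean()
print(
    f"\nmean smoothed gamma_hat, first tenth of anchors: {lo:.4f}"
    f"\nmean smoothed gamma_hat, last tenth of anchors:  {hi:.4f}"
    "\nThe indicator rises on approach to the bifurcation (escaped paths\n"
    "contribute only their pre-escape anchors, as in a real data stream)."
)
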