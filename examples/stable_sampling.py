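"""Sample symmetric alpha-stable variates and check them against the law.

Draws 10^5 variates for several tail indices alpha with the same seed, then
compares the empirical characteristic function with exp(-(gamma u)^alpha) and
shows that the heavy-tailed samples share their largest events (same base
draws), while their empirical second moment depends strongly on alpha.
"""

import numpy as np

from stableews import StableParams, empirical_abs_moment, sas_characteristic_function, sas_sample

n, gamma, seed = 100_000, 0.1, 1

print("alpha   ECF(u=1)  theory    max|Z|     mean Z^2")
for alpha in (2.0, 1.8, 1.5, 1.3):
    p = StableParams(alpha, gamma)
    z = sas_sample(n, p, seed)
    ecf = np.mean(np.cos(1.0 * z))
    print(
        f"{alpha:4.1f}   {ecf:8.5f}  {sas_characteristic_function(1.0, p):8.5f}"
        f"  {np.abs(z).max():9.2f}  {empirical_abs_moment(z, 2.0):10.6f}"
    )

print(
    "\nThe ECF matches the stable characteristic function for every alpha.\n"
    "At alpha=2 the mean square is ~2*gamma^2 = 0.02; for alpha<2 it is\n"
    "dominated by the largest jump (the second moment diverges), which is\n"
    "why variance is an unreliable statistic for heavy-tailed data."
)
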