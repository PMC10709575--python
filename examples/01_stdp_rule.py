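"""The plasticity rule in isolation.

Evaluates the two branches of the spike-timing-dependent update used at
the cue synapses: a Gaussian depression window centered at Δt = −24 ms
(pre after post), and a soft-bounded potentiation with a 2 ms e-folding
(post after pre).  Prints the weight change over a grid of pairing
intervals; the minimum of the depression multiplier and the potentiation
decay constant are the two numbers to look at.
"""

import numpy as np

from placesim.plasticity import (STDPParams, depression_update,
                                 potentiation_update)

params = STDPParams(g_peak_max=1.8)   # weights in units of g0 = 1
g0 = 1.0

print("Δt (ms)   relative weight change after one pairing (A = 0.2)")
A = 0.2
for dt in (-80.0, -40.0, -24.0, -10.0, -2.0, 2.0, 4.0, 8.0, 24.0):
    if dt < 0:
        A_new = depression_update(A, dt, params)
    else:
        A_new = potentiation_update(A, dt, g0, params)
    print(f"{dt:+7.1f}   {100 * (A_new - A) / A:+8.2f} %")

grid = np.arange(-100.0, -0.1, 0.1)
mult = np.array([depression_update(1.0, d, params) for d in grid])
print(f"\ndepression is strongest at Δt = {grid[np.argmin(mult)]:.1f} ms "
      f"(multiplier {mult.min():.4f})")
inc2 = potentiation_update(0.0, 2.0, g0, params)
inc4 = potentiation_update(0.0, 4.0, g0, params)
print(f"potentiation e-folding: increment(4 ms)/increment(2 ms) = "
      f"{inc4 / inc2:.4f}  (1/e = {np.exp(-1):.4f})")
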