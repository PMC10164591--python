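"""Fitting kinetic parameters back from a simulated time course.

Generates a burst-protocol data set at known parameters, then fits the
catalytic rate and the handoff rate by simulation-based least squares
with common random numbers.
"""

import numpy as np

import tailkin as tk
import tailkin.types as T

params = tk.KineticParams()          # truth: 25 nt/s per subunit, 0.1/s handoff
sub = T.tce_a70(conc=50.0)
enz = T.mini_complex(5.0)
effs = (T.smaug(300.0),)
grid = np.concatenate([np.arange(0.0, 6.0, 0.5), [8.0, 12.0, 20.0, 30.0]])

from tailkin.kinetics import simulate
data = simulate(sub, enz, effs, params, grid, n_molecules=4000, seed=10,
                pre_bound=True)
result = tk.fit_kinetic_params(
    tk.observed_summaries(data), ["k_cat_ccr4", "handoff_rate"],
    {"k_cat_ccr4": (5.0, 100.0), "handoff_rate": (0.01, 1.0)}, seed=11,
    base_params=params, substrate=sub, enzyme=enz, effectors=effs,
    n_molecules=4000, pre_bound=True)

print(result.to_frame().to_string(index=False))
print(f"\ntrue k_cat_ccr4 = 25 nt/s, true handoff_rate = 0.1 /s")
for name, truth in (("k_cat_ccr4", 25.0), ("handoff_rate", 0.1)):
    est = result.estimates[name]
    print(f"{name}: {est:.4g}  ({100*abs(est-truth)/truth:.1f}% off truth, "
          f"{result.profile_flags[name]})")
print("Both parameters are identified: the catalytic rate sets when the "
      "burst completes, the handoff rate sets the slope of the slow phase.")
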