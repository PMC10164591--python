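"""Processive burst: one RNA fully deadenylated per enzyme in seconds.

Simulates the burst protocol (5 nM deadenylase pre-engaged on 50 nM
SRE-containing RNA with 70-nt tails, Smaug tethering) and reads off the
burst-phase quantities.
"""

import numpy as np

import tailkin as tk

ens = tk.scenario("processive_burst", seed=1, n_molecules=20000)
table = tk.timecourse_table(ens)
print(table.to_string(index=False))

frac5 = table.loc[table.time_s == 5.0, "frac_deadenylated"].iloc[0]
amplitude = frac5 * 50.0
print(f"\nfraction fully deadenylated at 5 s: {frac5:.3f}")
print(f"burst amplitude: {amplitude:.2f} nM -> "
      f"{tk.burst_stoichiometry(amplitude, 5.0):.2f} RNA per enzyme complex")
print("A value near 1 means each enzyme strips one whole tail without "
      "dissociating, the signature of processive deadenylation; the slow "
      "later rise reflects the rate-limiting handoff to new substrates.")
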