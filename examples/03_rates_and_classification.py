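"""Rate estimation and the processive-vs-distributive verdict.

Quantifies the SRE-dependent stimulation by Smaug (wild-type vs mutated
binding sites) and classifies an enzyme titration of the unassisted
complex.
"""

import tailkin as tk
from tailkin.rates import endproduct_rate
from tailkin.scenarios import distributive_titration_ensembles

wt = tk.scenario("smaug_sre_wt", seed=3, n_molecules=2000)
mut = tk.scenario("smaug_sre_mut", seed=4, n_molecules=2000)
r = {}
for name, ens in (("SRE wild type", wt), ("SRE mutant", mut)):
    t = tk.timecourse_table(ens)
    r[name] = endproduct_rate(t.time_s / 60.0, t.frac_deadenylated,
                              ens.substrate.initial_conc)
    print(f"{name}: end product accumulates at {r[name]:.3f} nM/min")
print(f"SRE dependence: {r['SRE wild type']/r['SRE mutant']:.0f}-fold stimulation "
      "(Smaug only tethers the deadenylase to intact binding sites)\n")

series = distributive_titration_ensembles(5, n_molecules=1500)
report = tk.report_from_titration(series)
print(f"unassisted enzyme titration: coexistence index "
      f"{report.coexistence_index:.3f}, first-appearance ratio "
      f"{report.invariance_ratio:.1f} over an 8-fold titration")
print(f"verdict: {report.verdict}")
print("End product appears earlier at higher enzyme concentration and never "
      "coexists with untouched substrate: single nucleotides are removed "
      "per binding event (distributive mechanism).")
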