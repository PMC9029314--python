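"""Thermal stabilization and esterase-like activity of the liganded protein.

Compares apo and drug-bound thermal melts (fluorescence at 343 nm,
25-80 C) and classifies the drug's effect on the protein's esterase-like
hydrolysis of p-nitrophenyl acetate.
"""

import numpy as np

from albind import compare_thermal, esterase_rates, simulate_esterase, simulate_thermal

apo, cpx = simulate_thermal(Tm_C=58.0, dTm_C=5.0)
rep = compare_thermal(apo, cpx)
idx45 = int(np.argmin(np.abs(rep.temps_C - 45.0)))
print(f"normalized FI ratio (complex/apo) at 45 C: {rep.ratio[idx45]:.3f}")
print(f"melt midpoints: apo {rep.Tm_apo_C:.1f} C, complex {rep.Tm_complex_C:.1f} C "
      f"(dTm = {rep.dTm_C:+.1f} C)")
print(f"stabilized: {rep.stabilized}")
print("  the bound drug couples binding and unfolding equilibria, shifting\n"
      "  the melt to higher temperature\n")

result = esterase_rates(simulate_esterase())
print("drug (uM):", [round(c * 1e6) for c in result.drug_conc])
print("relative esterase activity:", [round(r, 3) for r in result.relative_activity])
print(f"classification: {result.call.value}")
print("  initial p-nitrophenol formation rates are unchanged across\n"
      "  0-75 uM drug: binding does not block the catalytic site.")
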