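"""Binding constants, stoichiometry and van 't Hoff thermodynamics.

Fits the double-log plot log[(F0-F)/F] vs log[Q] at each temperature for
Kb and n, then the van 't Hoff line ln Kb vs 1/T for the enthalpy and
entropy of binding, with Gibbs energies and the dominant-force call.
"""

from albind import (
    GroundTruth,
    classify_forces,
    fit_double_log,
    fit_vant_hoff,
    simulate_temperature_family,
)

truth = GroundTruth(noise_sd=0.0)
family = simulate_temperature_family(truth)

fits = [fit_double_log(series) for series in family]
print("T (K)   Kb (1e4/M)   n      R^2")
for f in fits:
    print(f"{f.temperature_K:5.0f}   {f.Kb / 1e4:10.3f}   {f.n_stoich:.3f}  {f.r_squared:.4f}")

thermo = fit_vant_hoff(fits)
print(f"\ndH = {thermo.dH_J / 1e3:+.2f} kJ/mol   dS = {thermo.dS_J:+.1f} J/K/mol")
for e in thermo.per_T:
    print(
        f"  {e.temperature_K:.0f} K: TdS = {e.TdS_J / 1e3:6.2f} kJ/mol,"
        f"  dG = {e.dG_J / 1e3:6.2f} kJ/mol"
    )
force = classify_forces(thermo.dH_J, thermo.dS_J)
print(f"spontaneous: {thermo.spontaneous}, exothermic: {thermo.exothermic}")
print(f"dominant force by sign rule: {force.label.value}")
print(
    "\nNegative dG at every temperature means binding is spontaneous; the\n"
    "(dH < 0, dS > 0) sign pattern points to electrostatic interactions."
)
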