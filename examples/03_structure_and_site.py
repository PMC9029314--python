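"""Structural probes: UV-Vis shift, synchronous fluorescence, CD, site markers.

Builds synthetic UV titration spectra, synchronous scans, CD spectra and
site-marker displacement curves, then runs each structural analysis.
"""

from albind import (
    GroundTruth,
    analyze_sync_shift,
    analyze_uv_titration,
    cd_record,
    predict_binding_site,
    simulate_cd,
    simulate_displacement,
    simulate_sync_spectra,
    simulate_uv_titration,
)

truth = GroundTruth(noise_sd=0.0)

uv = analyze_uv_titration(simulate_uv_titration(truth))
print(f"UV 280 nm band: trend={uv.intensity_trend.value}, "
      f"shift={uv.total_shift_nm:+.1f} nm ({uv.direction.value})")
print("  hyperchromicity + blue shift = ground-state complex formation\n")

sync = analyze_sync_shift(
    simulate_sync_spectra(quench_factors=(1.0, 0.9, 0.8, 0.7)), delta_lambda=60
)
print(f"Synchronous dL=60 ({sync.residue}): trend={sync.intensity_trend.value}, "
      f"direction={sync.direction.value}")
print("  intensity falls with no peak shift: the tryptophan\n"
      "  microenvironment is unchanged by binding\n")

for label, frac in (("apo", 0.5592), ("complex", 0.4888)):
    rec = cd_record(simulate_cd(frac), protein_conc=5e-6, n_residues=585, path_length_cm=1.0)
    print(f"CD {label:8s}: MRE208 = {rec.mre:9.1f} deg cm^2/dmol -> helix {rec.helix_pct:.2f}%")
print("  binding costs ~7 percentage points of alpha-helix\n")

site = predict_binding_site(simulate_displacement())
print("site-marker terminal I%:",
      {m.value: round(v, 1) for m, v in site.terminal_I_pct.items()})
print(f"predicted binding site: {site.site} (subdomain {site.subdomain})")
print("  hemin displaces the drug far more than warfarin or ibuprofen,\n"
      "  so the drug occupies site III in subdomain IB.")
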