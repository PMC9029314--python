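# albind

Spectroscopic analysis of small-molecule binding to serum albumin.

Human serum albumin (HSA, 585 residues) is the main drug carrier in
plasma; how strongly and where a drug binds it controls the drug's free
concentration, distribution and half-life. `albind` turns the raw
measurements of a classic HSA-binding characterisation — fluorescence
quenching titrations, UV-Vis and synchronous spectra, circular
dichroism, site-marker competition, thermal melts and esterase kinetics
— into the quantities such a study reports, and ships synthetic-data
generators so every stage can be exercised and validated without an
instrument.

## The analysis

**Quenching.** Titrating HSA (5 µM) with a quencher Q reduces the
tryptophan emission. After inner-filter correction
(F·10^((A_ex+A_em)/2)), the Stern–Volmer plot

    F₀/F = 1 + K_SV[Q],        k_q = K_SV/τ₀   (τ₀ = 10⁻⁸ s)

gives the quenching constant per temperature. K_SV falling with
temperature together with k_q above the diffusion-collision limit
(2×10¹⁰ M⁻¹s⁻¹) identifies *static* quenching — a ground-state complex.

**Binding and thermodynamics.** The double-log plot

    log[(F₀−F)/F] = log K_b + n·log[Q]

yields the binding constant K_b and stoichiometry n; the van 't Hoff
line ln K_b = −ΔH⁰/RT + ΔS⁰/R yields the binding enthalpy and entropy,
ΔG⁰ = ΔH⁰ − TΔS⁰ the spontaneity, and the sign pattern of (ΔH⁰, ΔS⁰)
the dominant force: (+,+) hydrophobic, (−,−) van der Waals / H-bonding,
(−,+) electrostatic.

**Structure and site.** Mean residue ellipticity
MRE = θ_obs/(10·c·n·l) and the 208 nm helix calibration
helix% = (−MRE₂₀₈ − 4000)/(29000)·100 quantify secondary-structure
change; synchronous scans (Δλ = 15/60 nm → Tyr/Trp) and the 280 nm UV
band report the aromatic microenvironment; competition with warfarin
(Sudlow site I), ibuprofen (site II) and hemin (site III) locates the
binding site via I% = 100·F₂/F₁.

**Stability and function.** Two-state melt comparison (fluorescence at
343 nm, 25–80 °C) measures ligand-induced thermal stabilization (ΔTm);
initial rates of p-nitrophenyl acetate hydrolysis (A₄₀₀) classify the
effect on HSA's esterase-like activity.

## Worked example

```bash
python examples/01_quenching_mechanism.py
```

prints, for a noiseless synthetic three-temperature titration:

```
T (K)   Ksv (1e4/M)   kq (1e12/M/s)   R^2
  295         1.325           1.325   1.0000
  305         1.238           1.238   1.0000
  310         1.199           1.199   1.0000

mechanism: static
```

K_SV decreases with temperature and every k_q is ~65× the collision
limit, so the drug quenches by ground-state complex formation. The
other examples continue the story: `02` fits K_b ≈ 1.33×10⁴ M⁻¹ with
n ≈ 1 and ΔH⁰ = −5.09 kJ/mol, ΔS⁰ = +61.7 J/K/mol (spontaneous,
exothermic, electrostatic by the sign rule); `03` shows 280 nm
hyperchromicity with a blue shift, no synchronous peak shift, an
α-helix drop from 55.92% to 48.88%, and hemin winning the displacement
competition (binding site III, subdomain IB); `04` finds ΔTm = +5 °C
and no esterase inhibition; `05` aggregates everything into a single
JSON report.

The same pipeline runs from the shell:

```bash
albind simulate --out study --seed 0      # write a synthetic study
albind report --study study --out report.json --tables tables/
```

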