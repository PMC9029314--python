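# Methods

This note records the models behind each analysis stage, the synthetic
data they are validated against, and the numerical and design choices
that were genuinely open.

## Models and assumptions

**Static 1:1 quenching.** The whole quenching/binding chain assumes a
ground-state 1:1 protein–ligand complex with negligible ligand
depletion (free [Q] ≈ total [Q]; at 5 µM protein and K ≈ 10⁴ M⁻¹ the
bound fraction of ligand is a few percent, so the approximation is
consistent with the fitted constants). Under it the Stern–Volmer
constant *is* the association constant, and the double-log plot reduces
to the same model with slope n = 1 — a property the tests exploit: data
generated from F = F₀/(1 + K[Q]) must come back from `fit_double_log`
with n ≈ 1 and K_b ≈ K_SV.

**Regression conventions.** All straight-line fits are ordinary least
squares with a free intercept (`scipy.stats.linregress`). For the
Stern–Volmer plot the free intercept is diagnostic: it should be 1, and
deviations expose baseline or inner-filter problems that a
forced-through-1 fit would hide. The double-log plot uses base-10
logarithms (K_b = 10^intercept); the van 't Hoff plot uses natural
logarithms. Mixing the bases rescales K_b silently, so the code keeps
them strictly apart. Reported standard errors are the usual OLS slope
errors; 95% intervals in the tests use the Student-t quantile with
n − 2 degrees of freedom, the correct construction for an 8-point line.

**Inner-filter correction.** Observed fluorescence is corrected as
F_corr = F_obs · 10^((A_ex + A_em)/2) (the standard half-absorbance
geometric correction). The generators can apply the inverse attenuation
so the correction is testable as an exact round trip.

**Mechanism call.** `static` requires K_SV strictly decreasing with
temperature *and* every k_q = K_SV/τ₀ (τ₀ = 10⁻⁸ s for biopolymers)
above the scattering-collision limit 2×10¹⁰ M⁻¹s⁻¹; `dynamic` the
strict opposite; everything else — ties, non-monotone trends, mixed k_q
evidence — is `ambiguous` with the failing conditions listed. Ties are
never silently promoted to a mechanism.

**Force classification.** The (sign ΔH⁰, sign ΔS⁰) table: (+,+)
hydrophobic, (−,−) van der Waals/hydrogen bonding, (−,+) electrostatic.
(+,−) and exact zeros are `unclassified`; all nine sign combinations
are covered by tests.

**CD helix content.** MRE = θ_obs/(10·c·n·l) with θ_obs in millidegrees,
c molar, n = 585 residues, l in cm. The helix calibration as commonly
printed, ([MRE₂₀₈ − 4000]/29000)·100, yields negative percentages for
the (negative) 208 nm band; this package uses the standard −MRE₂₀₈
convention, helix% = (−MRE₂₀₈ − 4000)/29000 · 100, under which the
reference percentages 55.92% / 48.88% are reproduced exactly.
Out-of-range percentages are returned as computed with a warning, never
clamped, so calibration problems stay visible.

**Site assignment.** The winning marker is the one with the lowest
residual I% at the highest concentration common to all curves. If the
two most-displacing markers lie within the margin (default 5 percentage
points) the call is `indeterminate` rather than a coin flip.

**Thermal comparison.** Both melts are normalised to their 25 °C values
before comparison, because the scientific claim is about the *shape* of
the decline, not absolute brightness. `stabilized` requires the
normalised complex/apo ratio to exceed 1 over a contiguous band (≥2
grid points) containing 45 °C — a temperature where the apo protein has
begun to unfold but the complex has not. The optional two-state sigmoid
fit (scipy `curve_fit`, initialised at the half-transition temperature,
coarse grid-search fallback) reports midpoints and ΔTm.

**Esterase rates.** Initial rate = OLS slope of A₄₀₀(t) over the first
60% of the time window (rates are invariant to constant baselines).
Classification relative to the zero-drug rate: all activities within
[0.9, 1.1] → `no_inhibition`; any above 1.1 → `activation`; otherwise
`inhibition`, with a flag recording whether the decrease is monotone in
drug concentration (the three-way call has no separate label for a
non-monotone dip, so monotonicity is evidence, not a gate).

## Synthetic data: what it emulates, what it does not

Generators invert the estimators' models: quenching via
F = F₀/(1 + K[Q])·(1 + ε) on the 0–35 µM grid in 5 µM steps at
295/305/310 K, with the per-temperature constant given by
K(T) = exp(−ΔH⁰/RT + ΔS⁰/R); synchronous/UV bands as Gaussians with
prescribed scaling and (blue) shifts; CD as two overlapping negative
bands whose 208 nm value encodes the helix fraction exactly;
displacement as saturating competition F₂ = F₁(1 − d[M]/(K_d + [M]));
melts as two-state sigmoids; esterase as linear progress curves.

Noise is multiplicative Gaussian on intensities (default 1% relative):
photometric noise grows with signal, and at plausible levels intensities
stay positive. Default ground-truth parameters mirror the reference
drug–HSA system: K_SV = 0.7×10⁴ M⁻¹ at 295 K for single-temperature
simulations, K_b = 1.326×10⁴ M⁻¹, and the van 't Hoff pair
(ΔH⁰ = −5091.2 J/mol, ΔS⁰ = 61.658 J/K/mol) obtained by fitting the
measured K_b(T) family, which regenerates it to printed precision. The
apo helix fraction is 0.5592 (0.4888 for the complex), the melt
midpoint 58 °C with a +5 °C ligand shift and ~4 °C transition width,
marker strengths hemin 0.45 ≫ warfarin 0.12 > ibuprofen 0.08 with
K_d = 10 µM, and esterase factors 1.0 over 0–75 µM drug.

What passing tests therefore show: the estimators invert their
generative models exactly (noiseless closure ≤10⁻⁶ relative), behave
sensibly under photometric noise (near-unbiased K_SV, honest CIs,
RMSE shrinking with noise), and the categorical calls recover injected
ground truth. What they do not show: robustness to the pathologies of
real instruments — scatter peaks, baseline drift, lamp fluctuation,
ligand absorbance overlapping the emission band beyond the modelled
inner-filter attenuation, or deviations from 1:1 binding.

## Identifiability of the van 't Hoff fit, and the acceptance script

With K(T) spanning only ~10% across 295–310 K, the thermodynamic fit is
poorly conditioned: at 1% noise a single replicate's (ΔH⁰, ΔS⁰) can
even change sign. Two standard remedies are used in
`scripts/acceptance.py` and documented as the package's own choices:
titrations are signal-averaged over 32 replicates before fitting
(problem size: 3 temperatures × 8 points × 32 replicates), and the
reported (ΔH⁰, ΔS⁰) come from the van 't Hoff line over the
Stern–Volmer constants, which under the static model estimate the same
association constant but avoid the double-log intercept extrapolation.
That extrapolation — the intercept sits ~4.9 decades below the measured
log[Q] range — makes 10^intercept heavy-tailed under noise; K_b point
estimates at a single temperature are reported as computed, but their
Monte-Carlo mean is not a reliable summary (the median or geometric
mean is closer, and the tests measure this directly).

## Degenerate inputs and tie-breaks

Constant-fluorescence titrations return K_SV = 0 with a `zero_slope`
flag and R² reported as 0 (the regression R² is undefined). Nonzero
points with F ≥ F₀ are dropped from the double-log fit with a warning
(their quenched fraction is undefined); anti-quenching in the
Stern–Volmer fit warns but keeps the points so the diagnostics expose
the problem. Peak positions are read off the raw grid (argmax within
the band window ±20 nm for UV); a 5-point moving-average smoother is
available but off by default; shifts below 1 nm (the grid resolution)
are reported as `none`. Unit handling is exact: input files carry µM,
internal state is molar, and the writer divides by the reader's
conversion factor so file round trips are bit-stable.

## Known limitations

- Ligand depletion is ignored everywhere (valid for weak-to-moderate
  binding at these concentrations; wrong for K ≳ 10⁶ M⁻¹).
- The double-log K_b estimator's heavy-tailed noise behaviour is
  inherited from the method itself, not fixed here.
- The CD helix calibration is the two-point 208 nm formula; no
  basis-set deconvolution.
- Synchronous analysis tracks the global emission maximum; overlapping
  bands would need windowed tracking.
- The site call is ordinal (which marker displaces most); it does not
  model ternary equilibria or marker affinities.
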