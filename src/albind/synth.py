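"""Synthetic assay data from known ground truth, for offline pipeline testing.

Every generator inverts the model its matching estimator fits, so a
noiseless generate-then-fit round trip recovers the injected parameters
to numerical precision, and Monte-Carlo runs at realistic noise measure
estimator bias.  Defaults emulate the study conditions of a quetiapine /
human-serum-albumin titration: 5 uM protein, ligand 0-35 uM in 5 uM
steps, three temperatures (295/305/310 K), static 1:1 ground-state
complexation with negligible ligand depletion, and multiplicative
Gaussian photometric noise (fluorescence noise grows with signal, and
stays positive at plausible noise levels).

The ground-truth binding parameters mirror the fitted constants of that
system: Ksv 0.7e4 M^-1 at 295 K, Kb 1.326e4 M^-1, and a van 't Hoff pair
(dH = -5091.2 J/mol, dS = 61.658 J/K/mol) that reproduces the measured
Kb(T) family.  Determinism contract: the same GroundTruth (including its
seed) always yields bit-identical data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    GAS_CONSTANT,
    HSA_N_RESIDUES,
    Spectrum,
    SpectrumKind,
    TitrationPoint,
    TitrationSeries,
    ValidationError,
)
from .stability import ProgressCurve, ThermalProfile, two_state_melt
from .structure import DisplacementCurve, Marker, helix_to_mre208

__all__ = [
    "GroundTruth",
    "DEFAULT_CONC_GRID_M",
    "DEFAULT_TEMPS_K",
    "kb_at_temperature",
    "simulate_quench_titration",
    "simulate_temperature_family",
    "simulate_uv_titration",
    "simulate_sync_spectra",
    "simulate_cd",
    "simulate_displacement",
    "simulate_thermal",
    "simulate_esterase",
]

#: Ligand 0-35 uM in 5 uM steps (M).
DEFAULT_CONC_GRID_M = tuple(c * 1e-6 for c in (0, 5, 10, 15, 20, 25, 30, 35))

#: Temperatures of the titration family (K).
DEFAULT_TEMPS_K = (295.0, 305.0, 310.0)


@dataclass(frozen=True)
class GroundTruth:
    """Injected parameters for all synthetic assays.

    ``dH_J``/``dS_J`` drive the temperature dependence of the static
    quenching constant via the van 't Hoff relation; ``noise_sd`` is the
    relative (multiplicative) noise level on intensities.
    """

    Ksv_M: float = 0.7e4
    Kb_M: float = 1.326e4
    n_stoich: float = 1.0
    dH_J: float = -5091.2
    dS_J: float = 61.658
    helix_frac: float = 0.5592
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.Ksv_M > 0 and self.Kb_M > 0):
            raise ValidationError("Ksv and Kb must be > 0")
        if not 0.0 <= self.helix_frac <= 1.0:
            raise ValidationError("helix_frac must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def _rng(truth: GroundTruth, stream: int) -> np.random.Generator:
    # independent, reproducible stream per assay type
    return np.random.default_rng([truth.seed, stream])


def _mult_noise(rng: np.random.Generator, values: np.ndarray, sd: float) -> np.ndarray:
    if sd == 0.0:
        return values
    return values * (1.0 + rng.normal(0.0, sd, size=values.shape))


def kb_at_temperature(dH_J: float, dS_J: float, T_K: float) -> float:
    """Van 't Hoff closed form: Kb(T) = exp(-dH/(R T) + dS/R)."""
    return math.exp(-dH_J / (GAS_CONSTANT * T_K) + dS_J / GAS_CONSTANT)


# ---------------------------------------------------------------------------
# Fluorescence quenching
# ---------------------------------------------------------------------------


def simulate_quench_titration(
    truth: GroundTruth,
    conc_grid: Sequence[float] = DEFAULT_CONC_GRID_M,
    F0: float = 1000.0,
    temperature_K: float = 295.0,
    ife_absorbances: tuple[Sequence[float], Sequence[float]] | None = None,
    Ksv: float | None = None,
    _stream: int = 1,
) -> TitrationSeries:
    """Static-quenching titration: F = F0 / (1 + Ksv [Q]) x (1 + noise).

    ``conc_grid`` must include 0 (the F0 point).  If ``ife_absorbances``
    (A_ex, A_em per point) is given, the observed intensities are further
    attenuated by 10^(-(A_ex+A_em)/2), producing data that needs the
    inner-filter correction.
    """
    conc = np.asarray(conc_grid, dtype=float)
    if np.any(conc < 0):
        raise ValidationError("concentrations must be >= 0")
    if not np.any(conc == 0.0):
        raise ValidationError("conc_grid must include 0 (the F0 point)")
    conc = np.sort(conc)
    ksv = truth.Ksv_M if Ksv is None else Ksv
    f = F0 / (1.0 + ksv * conc)
    f = _mult_noise(_rng(truth, _stream), f, truth.noise_sd)
    if ife_absorbances is not None:
        a_ex = np.broadcast_to(np.asarray(ife_absorbances[0], dtype=float), conc.shape)
        a_em = np.broadcast_to(np.asarray(ife_absorbances[1], dtype=float), conc.shape)
        f = f * 10.0 ** (-(a_ex + a_em) / 2.0)
    points = tuple(TitrationPoint(float(c), float(v)) for c, v in zip(conc, f))
    return TitrationSeries(points, temperature_K=temperature_K)


def simulate_temperature_family(
    truth: GroundTruth,
    temps_K: Sequence[float] = DEFAULT_TEMPS_K,
    conc_grid: Sequence[float] = DEFAULT_CONC_GRID_M,
    F0: float = 1000.0,
) -> list[TitrationSeries]:
    """One static-quenching titration per temperature.

    The quenching constant at each T is the van 't Hoff binding constant
    Kb(T) = exp(-dH/(R T) + dS/R): for an exothermic complex (dH < 0) the
    fitted Ksv then falls with temperature, the static signature.
    """
    temps = [float(t) for t in temps_K]
    if len(set(temps)) < 2:
        raise ValidationError("need >= 2 distinct temperatures")
    out = []
    for i, t in enumerate(sorted(temps)):
        k = kb_at_temperature(truth.dH_J, truth.dS_J, t)
        out.append(
            simulate_quench_titration(
                truth, conc_grid, F0=F0, temperature_K=t, Ksv=k, _stream=100 + i
            )
        )
    return out


# ---------------------------------------------------------------------------
# UV-Vis
# ---------------------------------------------------------------------------


def simulate_uv_titration(
    truth: GroundTruth,
    conc_grid: Sequence[float] = DEFAULT_CONC_GRID_M,
    A280_0: float = 0.5,
    hyperchromicity: float = 0.4,
    blue_shift_total_nm: float = 3.0,
    band_center_nm: float = 280.0,
    band_width_nm: float = 18.0,
    grid_nm: Sequence[float] | None = None,
) -> list[Spectrum]:
    """Aromatic-band absorbance spectra with saturating hyperchromicity.

    The 280 nm absorbance grows as A = A0 (1 + h [Q]/(Kd + [Q])) with
    Kd = 1/Kb (binding-site saturation), while the band centre translates
    toward shorter wavelengths, linearly in the bound fraction, by
    ``blue_shift_total_nm`` in total.
    """
    conc = np.sort(np.asarray(conc_grid, dtype=float))
    if np.any(conc < 0):
        raise ValidationError("concentrations must be >= 0")
    if grid_nm is None:
        grid_nm = np.arange(240.0, 411.0, 1.0)
    wl = np.asarray(grid_nm, dtype=float)
    kd = 1.0 / truth.Kb_M
    rng = _rng(truth, 2)
    spectra = []
    for c in conc:
        bound = c / (kd + c)
        amp = A280_0 * (1.0 + hyperchromicity * bound)
        center = band_center_nm - blue_shift_total_nm * bound / (conc[-1] / (kd + conc[-1]) or 1.0)
        a = amp * np.exp(-0.5 * ((wl - center) / band_width_nm) ** 2)
        a = np.abs(_mult_noise(rng, a, truth.noise_sd))
        spectra.append(Spectrum(wl, a, SpectrumKind.UV_VIS))
    return spectra


# ---------------------------------------------------------------------------
# Synchronous fluorescence
# ---------------------------------------------------------------------------


def simulate_sync_spectra(
    peak_center_nm: float = 285.0,
    peak_width_nm: float = 12.0,
    quench_factors: Sequence[float] = (1.0, 0.9, 0.8, 0.7),
    shift_nm: float = 0.0,
    amplitude: float = 1000.0,
    grid_nm: Sequence[float] | None = None,
) -> list[Spectrum]:
    """Gaussian emission peaks scaled per addition and shifted cumulatively.

    ``shift_nm`` is the per-addition displacement of the peak centre; the
    i-th spectrum is shifted by i x shift_nm.
    """
    if peak_width_nm <= 0:
        raise ValidationError("peak width must be > 0")
    if grid_nm is None:
        lo = peak_center_nm - 60.0
        grid_nm = np.arange(lo, peak_center_nm + 61.0, 1.0)
    wl = np.asarray(grid_nm, dtype=float)
    spectra = []
    for i, q in enumerate(quench_factors):
        center = peak_center_nm + i * shift_nm
        inten = amplitude * q * np.exp(-0.5 * ((wl - center) / peak_width_nm) ** 2)
        spectra.append(Spectrum(wl, inten, SpectrumKind.SYNCHRONOUS))
    return spectra


# ---------------------------------------------------------------------------
# Circular dichroism
# ---------------------------------------------------------------------------


def simulate_cd(
    helix_frac: float,
    protein_conc: float = 5e-6,
    n_residues: int = HSA_N_RESIDUES,
    path_length_cm: float = 1.0,
    grid_nm: Sequence[float] | None = None,
) -> Spectrum:
    """Far-UV CD spectrum whose 208 nm ellipticity encodes the helix fraction.

    The spectrum is shaped as two overlapping negative bands (208 and
    222 nm); its millidegree value at 208 nm, normalised to MRE, inverts
    exactly to ``helix_frac`` through the helix calibration.
    """
    if not 0.0 <= helix_frac <= 1.0:
        raise ValidationError("helix_frac must lie in [0, 1]")
    if grid_nm is None:
        grid_nm = np.arange(200.0, 261.0, 1.0)
    wl = np.asarray(grid_nm, dtype=float)
    mre208 = helix_to_mre208(100.0 * helix_frac)
    theta208 = mre208 * 10.0 * protein_conc * n_residues * path_length_cm
    shape = np.exp(-0.5 * ((wl - 208.0) / 7.0) ** 2) + 0.95 * np.exp(
        -0.5 * ((wl - 222.0) / 9.0) ** 2
    )
    shape208 = np.exp(0.0) + 0.95 * np.exp(-0.5 * (14.0 / 9.0) ** 2)
    theta = theta208 * shape / shape208
    return Spectrum(wl, theta, SpectrumKind.CD)


# ---------------------------------------------------------------------------
# Site-marker displacement
# ---------------------------------------------------------------------------


def simulate_displacement(
    overlaps: dict[Marker | str, float] | None = None,
    Kd_marker: float = 10e-6,
    marker_grid: Sequence[float] = tuple(c * 1e-6 for c in (0, 5, 10, 15, 20, 25, 30)),
    F1_base: float = 800.0,
) -> list[DisplacementCurve]:
    """Marker competition curves F2([M]) = F1 (1 - d [M]/(Kd + [M])).

    ``overlaps`` maps each marker to its displacement strength d in
    [0, 1]; d = 0 leaves the drug untouched (I% = 100 throughout), larger
    d drives the terminal I% lower.  Defaults inject hemin as the
    dominant competitor (the drug sits in site III / subdomain IB).
    """
    if overlaps is None:
        overlaps = {Marker.HEMIN: 0.45, Marker.WARFARIN: 0.12, Marker.IBUPROFEN: 0.08}
    if Kd_marker <= 0:
        raise ValidationError("Kd_marker must be > 0")
    conc = np.sort(np.asarray(marker_grid, dtype=float))
    curves = []
    for marker, d in overlaps.items():
        if not 0.0 <= d <= 1.0:
            raise ValidationError("displacement strength d must lie in [0, 1]")
        f2 = F1_base * (1.0 - d * conc / (Kd_marker + conc))
        curves.append(DisplacementCurve(Marker(marker), conc, F1_base, f2))
    return curves


# ---------------------------------------------------------------------------
# Thermal melt
# ---------------------------------------------------------------------------


def simulate_thermal(
    Tm_C: float = 58.0,
    dTm_C: float = 5.0,
    temps_C: Sequence[float] | None = None,
    width_C: float = 4.0,
    fi_folded: float = 1000.0,
    fi_unfolded: float = 200.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ThermalProfile, ThermalProfile]:
    """Apo and complex melts; the complex midpoint is shifted by ``dTm_C``."""
    if temps_C is None:
        temps_C = np.arange(25.0, 81.0, 5.0)
    t = np.asarray(temps_C, dtype=float)
    rng = np.random.default_rng([seed, 7])
    apo = two_state_melt(t, fi_folded, fi_unfolded, Tm_C, width_C)
    cpx = two_state_melt(t, fi_folded, fi_unfolded, Tm_C + dTm_C, width_C)
    apo = _mult_noise(rng, apo, noise_sd)
    cpx = _mult_noise(rng, cpx, noise_sd)
    return (
        ThermalProfile(t, apo, label="apo"),
        ThermalProfile(t, cpx, label="complex"),
    )


# ---------------------------------------------------------------------------
# Esterase activity
# ---------------------------------------------------------------------------


def simulate_esterase(
    v0: float = 0.02,
    inhibition_factors: dict[float, float] | None = None,
    t_grid_min: Sequence[float] | None = None,
    baseline: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[ProgressCurve]:
    """Linear A400 progress curves: A(t) = v0 x factor x t + baseline.

    ``inhibition_factors`` maps drug concentration (M) to the fractional
    rate (1.0 = uninhibited); it must contain a zero-drug entry with
    factor 1.  Defaults emulate a drug with no effect on the esterase
    activity over 0-75 uM.
    """
    if v0 < 0:
        raise ValidationError("v0 must be >= 0")
    if inhibition_factors is None:
        inhibition_factors = {c * 1e-6: 1.0 for c in (0, 15, 30, 45, 60, 75)}
    if 0.0 not in inhibition_factors:
        raise ValidationError("a zero-drug entry is required")
    if t_grid_min is None:
        t_grid_min = np.arange(0.0, 10.5, 0.5)
    t = np.asarray(t_grid_min, dtype=float)
    if np.any(t < 0):
        raise ValidationError("times must be >= 0")
    rng = np.random.default_rng([seed, 8])
    curves = []
    for conc in sorted(inhibition_factors):
        a = v0 * inhibition_factors[conc] * t + baseline
        if noise_sd > 0:
            a = a + rng.normal(0.0, noise_sd * max(v0 * t[-1], 1e-12), size=a.shape)
        curves.append(ProgressCurve(float(conc), t, a))
    return curves
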