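"""Structural probes: UV-Vis band shifts, synchronous fluorescence,
circular dichroism helix content and competitive site-marker displacement.

UV-Vis hyperchromicity at the 280 nm aromatic band together with a blue
shift signals ground-state complex formation.  Synchronous scans at a
fixed excitation-emission offset isolate tyrosine (delta-lambda 15 nm)
or tryptophan (60 nm); a peak shift there reports a changed residue
microenvironment.  Far-UV CD quantifies alpha-helix via the mean residue
ellipticity at 208 nm,

    MRE = theta_obs / (10 c n l),
    helix% = 100 * (-MRE208 - 4000) / (33000 - 4000),

with theta_obs in millidegrees, c the molar protein concentration, n the
residue count and l the path length in cm.  The helix formula uses the
conventional sign (-MRE208): the 208 nm band is negative, and a deeper
band means more helix.  Site-marker competition compares how strongly
warfarin (Sudlow site I, subdomain IIA), ibuprofen (site II, IIIA) and
hemin (site III, IB) displace the bound drug; the marker causing the
lowest residual intensity I% = 100 F2/F1 locates the drug's site.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import Spectrum, ValidationError

__all__ = [
    "ShiftDirection",
    "IntensityTrend",
    "ShiftReport",
    "CDRecord",
    "Marker",
    "MARKER_SITES",
    "DisplacementCurve",
    "SiteCall",
    "analyze_uv_titration",
    "analyze_sync_shift",
    "mean_residue_ellipticity",
    "helix_content",
    "helix_to_mre208",
    "cd_record",
    "displacement_percent",
    "predict_binding_site",
]

#: Eq. constants of the helix calibration (deg cm^2 dmol^-1).
_MRE_COIL = -4000.0
_MRE_HELIX = -33000.0


class ShiftDirection(str, enum.Enum):
    BLUE = "blue"
    RED = "red"
    NONE = "none"


class IntensityTrend(str, enum.Enum):
    HYPERCHROMIC = "hyperchromic"
    HYPOCHROMIC = "hypochromic"
    FLAT = "flat"


@dataclass(frozen=True)
class ShiftReport:
    peak_positions_nm: tuple[float, ...]
    total_shift_nm: float
    direction: ShiftDirection
    intensity_trend: IntensityTrend
    #: 'Y' (tyrosine) or 'W' (tryptophan) for synchronous scans, else None
    residue: str | None = None


@dataclass(frozen=True)
class CDRecord:
    """Observed ellipticity at one wavelength plus its normalised quantities."""

    theta_obs_mdeg: float
    protein_conc: float
    n_residues: int
    path_length_cm: float
    mre: float
    helix_pct: float | None = None  # populated only for the 208 nm band


class Marker(str, enum.Enum):
    WARFARIN = "warfarin"
    IBUPROFEN = "ibuprofen"
    HEMIN = "hemin"


#: Marker -> (albumin site, subdomain)
MARKER_SITES: dict[Marker, tuple[str, str]] = {
    Marker.WARFARIN: ("Sudlow site I", "IIA"),
    Marker.IBUPROFEN: ("Sudlow site II", "IIIA"),
    Marker.HEMIN: ("site III", "IB"),
}


@dataclass(frozen=True)
class DisplacementCurve:
    """Fluorescence of the protein-drug system titrated with one site marker.

    F1 is the intensity with no marker; F2 the intensity at each marker
    concentration; I% = 100 F2/F1 pointwise (so I% = 100 at zero marker).
    """

    marker: Marker
    marker_conc: np.ndarray  # M, ascending, starts at 0
    F1: float
    F2: np.ndarray

    def __post_init__(self) -> None:
        conc = np.asarray(self.marker_conc, dtype=float)
        f2 = np.asarray(self.F2, dtype=float)
        if conc.size != f2.size or conc.size < 2:
            raise ValidationError("need matched marker_conc/F2 with >= 2 points")
        if conc[0] != 0.0 or not np.all(np.diff(conc) > 0):
            raise ValidationError("marker concentrations must start at 0 and increase")
        if self.F1 <= 0:
            raise ValidationError("F1 must be > 0")
        conc.setflags(write=False)
        f2.setflags(write=False)
        object.__setattr__(self, "marker", Marker(self.marker))
        object.__setattr__(self, "marker_conc", conc)
        object.__setattr__(self, "F2", f2)

    @property
    def I_pct(self) -> np.ndarray:
        return 100.0 * self.F2 / self.F1


@dataclass(frozen=True)
class SiteCall:
    winner: Marker | None
    site: str | None
    subdomain: str | None
    terminal_I_pct: dict[Marker, float]
    indeterminate: bool
    margin_pct: float


# ---------------------------------------------------------------------------
# Peak tracking
# ---------------------------------------------------------------------------


def _smooth5(y: np.ndarray) -> np.ndarray:
    kernel = np.ones(5) / 5.0
    pad = np.pad(y, 2, mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def _peak_position(spec: Spectrum, window: tuple[float, float] | None, smooth: bool) -> float:
    wl = spec.wavelength_nm
    inten = _smooth5(spec.intensity) if smooth else spec.intensity
    if window is not None:
        mask = (wl >= window[0]) & (wl <= window[1])
        if not mask.any():
            raise ValidationError("peak window lies outside the spectrum grid")
        wl, inten = wl[mask], inten[mask]
    return float(wl[int(np.argmax(inten))])


def _intensity_trend(values: np.ndarray) -> IntensityTrend:
    if np.ptp(values) == 0.0:
        return IntensityTrend.FLAT
    rho = stats.spearmanr(np.arange(values.size), values).statistic
    if np.isnan(rho) or rho == 0:
        return IntensityTrend.FLAT
    return IntensityTrend.HYPERCHROMIC if rho > 0 else IntensityTrend.HYPOCHROMIC


def _shift_report(
    spectra: Sequence[Spectrum],
    band_nm: float | None,
    window: tuple[float, float] | None,
    shift_threshold_nm: float,
    smooth: bool,
    residue: str | None = None,
) -> ShiftReport:
    if len(spectra) < 2:
        raise ValidationError("need >= 2 spectra to track a shift")
    grid = spectra[0].wavelength_nm
    for s in spectra[1:]:
        if s.wavelength_nm.size != grid.size or not np.array_equal(s.wavelength_nm, grid):
            raise ValidationError("spectra must share a common wavelength grid")
    peaks = tuple(_peak_position(s, window, smooth) for s in spectra)
    total = peaks[-1] - peaks[0]
    if abs(total) < shift_threshold_nm:
        direction = ShiftDirection.NONE
    else:
        direction = ShiftDirection.RED if total > 0 else ShiftDirection.BLUE
    if band_nm is None:
        band_values = np.array([s.intensity.max() for s in spectra])
    else:
        band_values = np.array([s.value_at(band_nm) for s in spectra])
    return ShiftReport(
        peak_positions_nm=peaks,
        total_shift_nm=float(total),
        direction=direction,
        intensity_trend=_intensity_trend(band_values),
        residue=residue,
    )


def analyze_uv_titration(
    spectra: Sequence[Spectrum],
    band_nm: float = 280.0,
    shift_threshold_nm: float = 1.0,
    smooth: bool = False,
) -> ShiftReport:
    """Track the aromatic absorbance band across a ligand titration.

    Intensity trend is read at ``band_nm`` (hyperchromic = rising);
    the peak is located as the argmax within ``band_nm`` +/- 20 nm, and the
    signed total displacement sets the shift direction (blue = shorter
    wavelengths), with sub-threshold shifts reported as 'none'.
    """
    return _shift_report(
        spectra,
        band_nm=band_nm,
        window=(band_nm - 20.0, band_nm + 20.0),
        shift_threshold_nm=shift_threshold_nm,
        smooth=smooth,
    )


def analyze_sync_shift(
    spectra: Sequence[Spectrum],
    delta_lambda: int,
    shift_threshold_nm: float = 1.0,
    smooth: bool = False,
) -> ShiftReport:
    """Synchronous-scan peak tracking; delta_lambda 15 -> Tyr, 60 -> Trp."""
    residues = {15: "Y", 60: "W"}
    if delta_lambda not in residues:
        raise ValidationError("delta_lambda must be 15 or 60 nm")
    return _shift_report(
        spectra,
        band_nm=None,  # trend from the (moving) emission maximum
        window=None,
        shift_threshold_nm=shift_threshold_nm,
        smooth=smooth,
        residue=residues[delta_lambda],
    )


# ---------------------------------------------------------------------------
# Circular dichroism
# ---------------------------------------------------------------------------


def mean_residue_ellipticity(
    theta_obs_mdeg: float,
    protein_conc: float,
    n_residues: int,
    path_length_cm: float,
) -> float:
    """MRE (deg cm^2 dmol^-1) from observed ellipticity in millidegrees."""
    if protein_conc <= 0 or n_residues <= 0 or path_length_cm <= 0:
        raise ValidationError("concentration, residue count and path length must be > 0")
    return theta_obs_mdeg / (10.0 * protein_conc * n_residues * path_length_cm)


def helix_content(mre208: float) -> float:
    """Alpha-helix percentage from MRE at 208 nm.

    100% corresponds to MRE208 = -33000, 0% to -4000.  Values outside
    [0, 100] are returned as computed, with a warning, so calibration
    problems stay visible.
    """
    if not np.isfinite(mre208):
        raise ValidationError("MRE208 must be finite")
    pct = 100.0 * (-mre208 + _MRE_COIL) / (_MRE_COIL - _MRE_HELIX)
    if pct < -1e-9 or pct > 100.0 + 1e-9:
        warnings.warn(f"helix content {pct:.2f}% outside [0, 100]", stacklevel=2)
    return pct


def helix_to_mre208(helix_pct: float) -> float:
    """Inverse of :func:`helix_content` (exact on [0, 100])."""
    return -(helix_pct / 100.0 * (_MRE_COIL - _MRE_HELIX) - _MRE_COIL)


def cd_record(
    spectrum: Spectrum,
    protein_conc: float,
    n_residues: int,
    path_length_cm: float,
    wavelength_nm: float = 208.0,
) -> CDRecord:
    """Read ellipticity off a CD spectrum and normalise to MRE (+ helix% at 208 nm)."""
    theta = spectrum.value_at(wavelength_nm)
    mre = mean_residue_ellipticity(theta, protein_conc, n_residues, path_length_cm)
    helix = helix_content(mre) if wavelength_nm == 208.0 else None
    return CDRecord(
        theta_obs_mdeg=theta,
        protein_conc=protein_conc,
        n_residues=n_residues,
        path_length_cm=path_length_cm,
        mre=mre,
        helix_pct=helix,
    )


# ---------------------------------------------------------------------------
# Site-marker displacement
# ---------------------------------------------------------------------------


def displacement_percent(F1: float, F2: float) -> float:
    """Residual intensity I% = 100 F2/F1 of the protein-drug system."""
    if F1 <= 0:
        raise ValidationError("F1 must be > 0")
    return 100.0 * F2 / F1


def predict_binding_site(
    curves: Sequence[DisplacementCurve],
    margin_pct: float = 5.0,
) -> SiteCall:
    """Assign the drug's binding site from competitive marker displacement.

    The winner is the marker with the lowest I% at the highest marker
    concentration common to all curves (greatest displacement).  If the
    two most-displacing markers differ by less than ``margin_pct``
    percentage points the call is indeterminate.
    """
    if len(curves) < 2:
        raise ValidationError("need >= 2 marker curves")
    markers = [c.marker for c in curves]
    if len(set(markers)) != len(markers):
        raise ValidationError("duplicate markers")
    top = min(float(c.marker_conc[-1]) for c in curves)
    if top <= 0:
        raise ValidationError("no common nonzero marker concentration")
    terminal: dict[Marker, float] = {}
    for c in curves:
        if top < c.marker_conc[0] or top > c.marker_conc[-1]:
            raise ValidationError("no common marker concentration")
        i_at_top = float(np.interp(top, c.marker_conc, c.I_pct))
        terminal[c.marker] = i_at_top
    ranked = sorted(terminal.items(), key=lambda kv: kv[1])
    if len(ranked) >= 2 and ranked[1][1] - ranked[0][1] < margin_pct:
        return SiteCall(None, None, None, terminal, True, margin_pct)
    winner = ranked[0][0]
    site, subdomain = MARKER_SITES[winner]
    return SiteCall(winner, site, subdomain, terminal, False, margin_pct)
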