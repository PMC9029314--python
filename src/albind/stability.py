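"""Thermal stabilization of the liganded protein and esterase-like activity.

Ligand binding couples to the unfolding equilibrium, so a bound drug
shifts the thermal melt of the protein to higher temperature.  The melt
is followed by tryptophan fluorescence at 343 nm over 25-80 C; profiles
of the apo protein and the drug complex are normalised to their 25 C
values and compared pointwise, and an optional two-state sigmoid fit
extracts midpoints (Tm) and the stabilization shift dTm.

Albumin also hydrolyses p-nitrophenyl acetate (esterase-like activity);
the product p-nitrophenol absorbs at 400 nm, so the initial slope of
A400(t) is the catalytic rate.  Rates at increasing drug concentration,
relative to the drug-free rate, classify the drug's functional effect.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .core import ValidationError

__all__ = [
    "ThermalProfile",
    "StabilizationReport",
    "ProgressCurve",
    "ActivityCall",
    "EsteraseResult",
    "two_state_melt",
    "fit_melt",
    "compare_thermal",
    "esterase_rates",
]


@dataclass(frozen=True)
class ThermalProfile:
    """Fluorescence at 343 nm vs. temperature for one sample ('apo' or 'complex')."""

    temps_C: np.ndarray
    fi343: np.ndarray
    label: str = "apo"

    def __post_init__(self) -> None:
        t = np.asarray(self.temps_C, dtype=float)
        f = np.asarray(self.fi343, dtype=float)
        if t.size != f.size or t.size < 3:
            raise ValidationError("profile needs matched grids with >= 3 points")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("temperature grid must be increasing")
        if t[0] < 25.0 - 1e-9 or t[-1] > 80.0 + 1e-9:
            raise ValidationError("temperature grid must lie within 25-80 C")
        if self.label not in ("apo", "complex"):
            raise ValidationError("label must be 'apo' or 'complex'")
        t.setflags(write=False)
        f.setflags(write=False)
        object.__setattr__(self, "temps_C", t)
        object.__setattr__(self, "fi343", f)


@dataclass(frozen=True)
class StabilizationReport:
    temps_C: np.ndarray
    ratio: np.ndarray  # normalised FI_complex / FI_apo
    stabilized: bool
    Tm_apo_C: float | None = None
    Tm_complex_C: float | None = None
    dTm_C: float | None = None


@dataclass(frozen=True)
class ProgressCurve:
    """A400 kinetic trace of p-nitrophenol formation at one drug concentration."""

    drug_conc: float  # M
    time_min: np.ndarray
    a400: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        a = np.asarray(self.a400, dtype=float)
        if t.size != a.size or t.size < 3:
            raise ValidationError("progress curve needs >= 3 matched time points")
        if np.any(t < 0) or not np.all(np.diff(t) > 0):
            raise ValidationError("times must be >= 0 and increasing")
        if self.drug_conc < 0:
            raise ValidationError("drug concentration must be >= 0")
        t.setflags(write=False)
        a.setflags(write=False)
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "a400", a)


class ActivityCall(str, enum.Enum):
    NO_INHIBITION = "no_inhibition"
    INHIBITION = "inhibition"
    ACTIVATION = "activation"


@dataclass(frozen=True)
class EsteraseResult:
    drug_conc: tuple[float, ...]
    initial_rate: tuple[float, ...]  # absorbance / min
    relative_activity: tuple[float, ...]
    call: ActivityCall
    monotone_decrease: bool


# ---------------------------------------------------------------------------
# Thermal melt
# ---------------------------------------------------------------------------


def two_state_melt(
    T_C: np.ndarray, fi_folded: float, fi_unfolded: float, Tm_C: float, width_C: float
) -> np.ndarray:
    """Two-state unfolding sigmoid: FI(T) = FI_f + (FI_u - FI_f)/(1 + exp((Tm - T)/w))."""
    T_C = np.asarray(T_C, dtype=float)
    return fi_folded + (fi_unfolded - fi_folded) / (1.0 + np.exp((Tm_C - T_C) / width_C))


def fit_melt(profile: ThermalProfile) -> tuple[float, float]:
    """Fit the two-state sigmoid; returns (Tm_C, width_C).

    Initialised at the half-transition temperature; falls back to a
    coarse grid search if the curvature fit fails to converge.
    """
    t, f = profile.temps_C, profile.fi343
    fi_f, fi_u = float(f[0]), float(f[-1])
    half = 0.5 * (fi_f + fi_u)
    tm0 = float(t[int(np.argmin(np.abs(f - half)))])
    try:
        popt, _ = optimize.curve_fit(
            two_state_melt, t, f, p0=[fi_f, fi_u, tm0, 3.0], maxfev=10000
        )
        return float(popt[2]), abs(float(popt[3]))
    except RuntimeError:
        grid = np.arange(t[0], t[-1] + 0.05, 0.1)
        widths = np.arange(0.5, 10.5, 0.5)
        best, best_sse = (tm0, 3.0), np.inf
        for tm in grid:
            for w in widths:
                sse = float(np.sum((two_state_melt(t, fi_f, fi_u, tm, w) - f) ** 2))
                if sse < best_sse:
                    best, best_sse = (float(tm), float(w)), sse
        return best


def compare_thermal(
    apo: ThermalProfile,
    complex: ThermalProfile,
    band_center_C: float = 45.0,
    fit_sigmoid: bool = True,
    ratio_rtol: float = 1e-9,
) -> StabilizationReport:
    """Compare apo and liganded melts after normalising each to its 25 C value.

    The complex counts as stabilized iff the normalised intensity ratio
    exceeds 1 over a contiguous temperature band containing
    ``band_center_C`` (default 45 C, where the apo protein has begun to
    unfold).  Absolute brightness differences cancel in the
    normalisation; only the shape of the decline matters.
    """
    if apo.temps_C.size != complex.temps_C.size or not np.array_equal(
        apo.temps_C, complex.temps_C
    ):
        raise ValidationError("profiles must share the temperature grid")
    norm_apo = apo.fi343 / apo.fi343[0]
    norm_cpx = complex.fi343 / complex.fi343[0]
    ratio = norm_cpx / norm_apo
    above = ratio > 1.0 + ratio_rtol
    idx = int(np.argmin(np.abs(apo.temps_C - band_center_C)))
    stabilized = bool(above[idx])
    if stabilized:
        # require the band to be contiguous around the center, not a lone blip
        lo = idx
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = idx
        while hi < above.size - 1 and above[hi + 1]:
            hi += 1
        stabilized = (hi - lo + 1) >= 2
    tm_a = tm_c = dtm = None
    if fit_sigmoid:
        tm_a, _ = fit_melt(apo)
        tm_c, _ = fit_melt(complex)
        dtm = tm_c - tm_a
    return StabilizationReport(
        temps_C=apo.temps_C,
        ratio=ratio,
        stabilized=stabilized,
        Tm_apo_C=tm_a,
        Tm_complex_C=tm_c,
        dTm_C=dtm,
    )


# ---------------------------------------------------------------------------
# Esterase activity
# ---------------------------------------------------------------------------


def esterase_rates(
    curves: Sequence[ProgressCurve],
    window_frac: float = 0.6,
    band: tuple[float, float] = (0.9, 1.1),
) -> EsteraseResult:
    """Initial rates and activity classification across drug concentrations.

    The initial rate is the least-squares slope of A400(t) over the first
    ``window_frac`` of the time window (rates are invariant to any
    constant baseline).  Relative to the drug-free rate: all activities
    inside ``band`` -> no_inhibition; any above -> activation; any below
    -> inhibition (with a flag recording whether the decrease is
    monotone in drug concentration).
    """
    if not curves:
        raise ValidationError("no progress curves supplied")
    curves = sorted(curves, key=lambda c: c.drug_conc)
    if curves[0].drug_conc != 0.0:
        raise ValidationError("a zero-drug progress curve is required")
    rates = []
    for c in curves:
        t0, t1 = c.time_min[0], c.time_min[-1]
        mask = c.time_min <= t0 + window_frac * (t1 - t0)
        if int(mask.sum()) < 3:
            mask = np.ones_like(c.time_min, dtype=bool)
        res = stats.linregress(c.time_min[mask], c.a400[mask])
        rates.append(float(res.slope))
    rate0 = rates[0]
    if rate0 == 0:
        raise ValidationError("zero-drug rate is zero; relative activity undefined")
    rel = np.array(rates) / rate0
    lo, hi = band
    monotone = bool(np.all(np.diff(rel) <= 1e-12))
    if np.all((rel >= lo) & (rel <= hi)):
        call = ActivityCall.NO_INHIBITION
    elif np.any(rel > hi):
        call = ActivityCall.ACTIVATION
    else:
        call = ActivityCall.INHIBITION
    return EsteraseResult(
        drug_conc=tuple(c.drug_conc for c in curves),
        initial_rate=tuple(rates),
        relative_activity=tuple(float(r) for r in rel),
        call=call,
        monotone_decrease=monotone,
    )
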