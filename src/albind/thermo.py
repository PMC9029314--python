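"""Binding constants, van 't Hoff thermodynamics and binding-force signs.

The double-logarithmic plot for static 1:1-like binding,

    log10[(F0 - F)/F] = log10 Kb + n log10 [Q],

gives the apparent binding constant Kb (from the intercept, base 10) and
the binding stoichiometry n (slope).  Fitting ln Kb against 1/T (van 't
Hoff) yields the standard enthalpy and entropy of binding,

    ln Kb = -dH/(R T) + dS/R,        dG(T) = dH - T dS,

and the sign pattern of (dH, dS) identifies the dominant non-covalent
force: (+,+) hydrophobic, (-,-) van der Waals / hydrogen bonding, (-,+)
electrostatic.  Note the deliberate mix of bases: the double-log plot is
base-10 as conventionally drawn, the van 't Hoff plot is natural log —
confusing the two rescales Kb silently.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import GAS_CONSTANT, TitrationSeries, ValidationError

__all__ = [
    "BindingFit",
    "PerTemperature",
    "ThermoResult",
    "BindingForce",
    "ForceCall",
    "fit_double_log",
    "fit_vant_hoff",
    "gibbs",
    "classify_forces",
]


@dataclass(frozen=True)
class BindingFit:
    """Apparent binding constant (M^-1) and stoichiometry from the double-log plot."""

    Kb: float
    n_stoich: float
    r_squared: float
    temperature_K: float

    def __post_init__(self) -> None:
        if not (self.Kb > 0 and self.n_stoich > 0):
            raise ValidationError("Kb and n must be > 0")


@dataclass(frozen=True)
class PerTemperature:
    temperature_K: float
    TdS_J: float
    dG_J: float
    #: |dG - (-R T ln Kb)|, reported (not enforced) consistency of the fit line
    #: with the pointwise free energy; None when no Kb was supplied at this T.
    dG_vs_lnKb_residual_J: float | None = None


@dataclass(frozen=True)
class ThermoResult:
    """Van 't Hoff enthalpy/entropy with per-temperature Gibbs energies.

    Invariants hold exactly: TdS_J = T * dS_J and dG_J = dH_J - TdS_J for
    every entry.  ``spontaneous`` is True iff dG < 0 at all input
    temperatures; ``exothermic`` iff dH < 0.
    """

    dH_J: float
    dS_J: float
    per_T: tuple[PerTemperature, ...]
    vant_hoff_r_squared: float
    R_gas: float = GAS_CONSTANT

    @property
    def spontaneous(self) -> bool:
        return all(e.dG_J < 0 for e in self.per_T)

    @property
    def exothermic(self) -> bool:
        return self.dH_J < 0


class BindingForce(str, enum.Enum):
    HYDROPHOBIC = "hydrophobic"
    VDW_HBOND = "vdw_hbond"
    ELECTROSTATIC = "electrostatic"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ForceCall:
    label: BindingForce
    signs: tuple[int, int]  # (sign dH, sign dS), each in {-1, 0, +1}


def fit_double_log(series: TitrationSeries) -> BindingFit:
    """Least squares of log10((F0-F)/F) on log10[Q]; Kb = 10^intercept, n = slope.

    The zero-concentration point only supplies F0.  Nonzero points with
    F >= F0 have no defined quenched fraction; they are dropped with a
    warning.  At least 3 usable points are required.
    """
    conc = series.concentrations
    f = series.intensities
    f0 = series.f0
    mask = (conc > 0) & (f < f0)
    dropped = int(((conc > 0) & ~(f < f0)).sum())
    if dropped:
        warnings.warn(
            f"dropping {dropped} point(s) with F >= F0 from double-log fit",
            stacklevel=2,
        )
    if int(mask.sum()) < 3:
        raise ValidationError("need at least 3 points with 0 < F < F0")
    x = np.log10(conc[mask])
    y = np.log10((f0 - f[mask]) / f[mask])
    res = stats.linregress(x, y)
    return BindingFit(
        Kb=float(10.0 ** res.intercept),
        n_stoich=float(res.slope),
        r_squared=float(res.rvalue) ** 2,
        temperature_K=series.temperature_K,
    )


def fit_vant_hoff(fits: list[BindingFit] | tuple[BindingFit, ...]) -> ThermoResult:
    """Linear van 't Hoff fit of ln Kb on 1/T.

    dH = -R * slope and dS = R * intercept; each input temperature gets a
    PerTemperature entry with TdS, dG = dH - T dS, and the reported
    residual against -R T ln Kb.
    """
    fits = sorted(fits, key=lambda f: f.temperature_K)
    if len(fits) < 2:
        raise ValidationError("van 't Hoff fit needs >= 2 temperatures")
    temps = np.array([f.temperature_K for f in fits])
    if np.unique(temps).size != temps.size:
        raise ValidationError("duplicate temperatures in van 't Hoff fit")
    kb = np.array([f.Kb for f in fits])
    x = 1.0 / temps
    y = np.log(kb)
    res = stats.linregress(x, y)
    dH = -GAS_CONSTANT * float(res.slope)
    dS = GAS_CONSTANT * float(res.intercept)
    r2 = 1.0 if len(fits) == 2 else float(res.rvalue) ** 2
    per_t = []
    for t, k in zip(temps, kb):
        tds = float(t) * dS
        dg = dH - tds
        per_t.append(
            PerTemperature(
                temperature_K=float(t),
                TdS_J=tds,
                dG_J=dg,
                dG_vs_lnKb_residual_J=abs(dg - (-GAS_CONSTANT * float(t) * math.log(k))),
            )
        )
    return ThermoResult(dH_J=dH, dS_J=dS, per_T=tuple(per_t), vant_hoff_r_squared=r2)


def gibbs(dH_J: float, dS_J: float, T_K: float) -> float:
    """Standard Gibbs energy dG = dH - T dS (J mol^-1)."""
    if T_K <= 0:
        raise ValidationError("temperature must be > 0 K")
    return dH_J - T_K * dS_J


def classify_forces(dH_J: float, dS_J: float) -> ForceCall:
    """Dominant binding force from the signs of dH and dS.

    (+,+) hydrophobic; (-,-) van der Waals + hydrogen bonding; (-,+)
    electrostatic; (+,-) and any exact zero are unclassified.
    """
    sh = int(np.sign(dH_J))
    ss = int(np.sign(dS_J))
    table = {
        (1, 1): BindingForce.HYDROPHOBIC,
        (-1, -1): BindingForce.VDW_HBOND,
        (-1, 1): BindingForce.ELECTROSTATIC,
    }
    return ForceCall(table.get((sh, ss), BindingForce.UNCLASSIFIED), (sh, ss))
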