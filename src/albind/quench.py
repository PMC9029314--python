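"""Stern–Volmer quenching analysis and mechanism classification.

The Stern–Volmer relation for collisional or apparent static quenching is

    F0 / F = 1 + Ksv [Q]

so the quenching constant Ksv is the slope of F0/F against quencher
concentration.  The bimolecular rate constant kq = Ksv / tau0 (tau0 the
unquenched fluorophore lifetime, 1e-8 s for biopolymers) discriminates
mechanisms: diffusion-limited collisional quenching cannot exceed the
scattering-collision limit of ~2e10 M^-1 s^-1, so kq far above it, together
with Ksv falling as temperature rises (ground-state complexes dissociate
when heated), indicates static quenching.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import DEFAULT_TAU0_S, TitrationSeries, ValidationError

__all__ = [
    "QuenchingFit",
    "Mechanism",
    "MechanismCall",
    "correct_inner_filter",
    "fit_stern_volmer",
    "classify_mechanism",
    "KQ_COLLISION_LIMIT",
]

#: Scattering-collision (diffusion) limit for biomolecular quenching, M^-1 s^-1.
KQ_COLLISION_LIMIT = 2e10


@dataclass(frozen=True)
class QuenchingFit:
    """Result of one Stern–Volmer regression.

    ``kq = Ksv / tau0`` exactly; ``intercept`` should be ~1 for well-behaved
    data.  ``zero_slope`` marks degenerate series (F constant), for which
    r_squared is reported as 0.
    """

    Ksv: float
    Ksv_se: float
    kq: float
    r_squared: float
    temperature_K: float
    intercept: float
    tau0_s: float = DEFAULT_TAU0_S
    zero_slope: bool = False


class Mechanism(str, enum.Enum):
    STATIC = "static"
    DYNAMIC = "dynamic"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class MechanismCall:
    mechanism: Mechanism
    #: one entry per temperature: (T, Ksv, kq, kq_above_threshold)
    evidence: tuple[tuple[float, float, float, bool], ...]
    reasons: tuple[str, ...] = ()


def correct_inner_filter(
    series: TitrationSeries,
    A_ex: float | np.ndarray,
    A_em: float | np.ndarray,
) -> TitrationSeries:
    """Undo inner-filter attenuation: F_corr = F_obs * 10^((A_ex + A_em)/2).

    ``A_ex``/``A_em`` are the sample absorbances at the excitation and
    emission wavelengths, either scalars or one value per titration point.
    """
    n = len(series)
    a_ex = np.broadcast_to(np.asarray(A_ex, dtype=float), (n,)) if np.ndim(A_ex) == 0 else np.asarray(A_ex, dtype=float)
    a_em = np.broadcast_to(np.asarray(A_em, dtype=float), (n,)) if np.ndim(A_em) == 0 else np.asarray(A_em, dtype=float)
    if a_ex.shape != (n,) or a_em.shape != (n,):
        raise ValidationError("absorbance lists must match the series length")
    if np.any(a_ex < 0) or np.any(a_em < 0):
        raise ValidationError("absorbances must be >= 0")
    factor = 10.0 ** ((a_ex + a_em) / 2.0)
    return series.with_intensities(series.intensities * factor)


def fit_stern_volmer(
    series: TitrationSeries,
    tau0_s: float = DEFAULT_TAU0_S,
    anti_quench_rtol: float = 1e-6,
) -> QuenchingFit:
    """Ordinary least squares of F0/F on [Q], free intercept.

    Requires at least 3 nonzero-concentration points.  Points where F
    exceeds F0 (anti-quenching, e.g. baseline drift) raise a warning but
    are kept; the regression itself is untouched so the fit diagnostics
    expose the problem.
    """
    if tau0_s <= 0:
        raise ValidationError("tau0_s must be > 0")
    conc = series.concentrations
    f = series.intensities
    f0 = series.f0
    nonzero = conc > 0
    if int(nonzero.sum()) < 3:
        raise ValidationError("need at least 3 nonzero-concentration points")
    if np.any(f[nonzero] > f0 * (1.0 + anti_quench_rtol)):
        warnings.warn(
            "fluorescence rises above F0 at nonzero quencher (anti-quenching)",
            stacklevel=2,
        )
    y = f0 / f
    if np.ptp(y) == 0.0:
        # F constant: no quenching at all; slope and R^2 degenerate.
        return QuenchingFit(
            Ksv=0.0,
            Ksv_se=0.0,
            kq=0.0,
            r_squared=0.0,
            temperature_K=series.temperature_K,
            intercept=float(y[0]),
            tau0_s=tau0_s,
            zero_slope=True,
        )
    res = stats.linregress(conc, y)
    ksv = float(res.slope)
    return QuenchingFit(
        Ksv=ksv,
        Ksv_se=float(res.stderr),
        kq=ksv / tau0_s,
        r_squared=float(res.rvalue) ** 2,
        temperature_K=series.temperature_K,
        intercept=float(res.intercept),
        tau0_s=tau0_s,
    )


def classify_mechanism(
    fits: list[QuenchingFit] | tuple[QuenchingFit, ...],
    kq_threshold: float = KQ_COLLISION_LIMIT,
) -> MechanismCall:
    """Static vs. dynamic quenching from the temperature trend of Ksv and kq.

    static  : Ksv strictly decreases with temperature AND every kq exceeds
              the collision limit.
    dynamic : Ksv strictly increases AND every kq is at or below the limit.
    Anything else — non-monotone Ksv, ties, or mixed kq evidence — is
    ambiguous, with the failing conditions listed in ``reasons``.
    """
    fits = sorted(fits, key=lambda f: f.temperature_K)
    if len(fits) < 2:
        raise ValidationError("mechanism classification needs >= 2 temperatures")
    temps = np.array([f.temperature_K for f in fits])
    if np.unique(temps).size != temps.size:
        raise ValidationError("duplicate temperatures in mechanism classification")
    ksv = np.array([f.Ksv for f in fits])
    kq = np.array([f.kq for f in fits])
    above = kq > kq_threshold
    evidence = tuple(
        (float(t), float(k), float(q), bool(a)) for t, k, q, a in zip(temps, ksv, kq, above)
    )
    decreasing = bool(np.all(np.diff(ksv) < 0))
    increasing = bool(np.all(np.diff(ksv) > 0))
    if decreasing and bool(above.all()):
        return MechanismCall(Mechanism.STATIC, evidence)
    if increasing and not bool(above.any()):
        return MechanismCall(Mechanism.DYNAMIC, evidence)
    reasons = []
    if not (decreasing or increasing):
        reasons.append("Ksv is not strictly monotone in temperature")
    if decreasing and not above.all():
        reasons.append("Ksv decreases but some kq <= collision limit")
    if increasing and above.any():
        reasons.append("Ksv increases but some kq > collision limit")
    return MechanismCall(Mechanism.AMBIGUOUS, evidence, tuple(reasons))
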