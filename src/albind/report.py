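"""Pipeline orchestration: run every analysis stage and aggregate a report.

``run_pipeline`` executes whatever stages have inputs (quenching ->
binding -> thermodynamics -> structural probes -> stability/activity)
and collects the results into a :class:`StudyReport`.  Stages without
inputs are reported as not run rather than silently omitted.  The JSON
serialisation carries explicit units on every numeric leaf and a
provenance block (input hashes, seed, package version); writing is
canonical, so identical inputs give byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    DEFAULT_TAU0_S,
    Assay,
    ExperimentManifest,
    FormatError,
    HSA_N_RESIDUES,
    Spectrum,
    SpectrumKind,
    TitrationSeries,
    ValidationError,
    read_manifest,
    read_spectrum,
    read_titration,
)
from .quench import (
    KQ_COLLISION_LIMIT,
    MechanismCall,
    QuenchingFit,
    classify_mechanism,
    fit_stern_volmer,
)
from .stability import (
    EsteraseResult,
    ProgressCurve,
    StabilizationReport,
    ThermalProfile,
    compare_thermal,
    esterase_rates,
)
from .structure import (
    CDRecord,
    DisplacementCurve,
    Marker,
    ShiftReport,
    SiteCall,
    analyze_sync_shift,
    analyze_uv_titration,
    cd_record,
    predict_binding_site,
)
from .thermo import BindingFit, ForceCall, ThermoResult, classify_forces, fit_double_log, fit_vant_hoff

__all__ = [
    "PipelineConfig",
    "StudyInputs",
    "StudyReport",
    "run_pipeline",
    "load_study",
    "save_report",
    "load_report",
    "write_summary_tables",
]


@dataclass(frozen=True)
class PipelineConfig:
    tau0_s: float = DEFAULT_TAU0_S
    kq_threshold: float = KQ_COLLISION_LIMIT
    site_margin_pct: float = 5.0
    uv_band_nm: float = 280.0
    seed: int | None = None


@dataclass
class StudyInputs:
    """In-memory inputs per assay; ``None`` means the assay was not measured."""

    quench_family: Sequence[TitrationSeries] | None = None
    uv_spectra: Sequence[Spectrum] | None = None
    sync15: Sequence[Spectrum] | None = None
    sync60: Sequence[Spectrum] | None = None
    cd_apo: Spectrum | None = None
    cd_complex: Spectrum | None = None
    cd_protein_conc: float = 5e-6
    cd_n_residues: int = HSA_N_RESIDUES
    cd_path_length_cm: float = 1.0
    displacement: Sequence[DisplacementCurve] | None = None
    thermal_apo: ThermalProfile | None = None
    thermal_complex: ThermalProfile | None = None
    esterase: Sequence[ProgressCurve] | None = None
    provenance: dict = field(default_factory=dict)


@dataclass
class StudyReport:
    quenching: list[QuenchingFit] | None = None
    mechanism: MechanismCall | None = None
    binding: list[BindingFit] | None = None
    thermodynamics: ThermoResult | None = None
    forces: ForceCall | None = None
    uv_shift: ShiftReport | None = None
    sync15_shift: ShiftReport | None = None
    sync60_shift: ShiftReport | None = None
    cd_apo: CDRecord | None = None
    cd_complex: CDRecord | None = None
    site: SiteCall | None = None
    stabilization: StabilizationReport | None = None
    esterase: EsteraseResult | None = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return _report_to_dict(self)


def run_pipeline(inputs: StudyInputs, config: PipelineConfig = PipelineConfig()) -> StudyReport:
    """Run all stages whose inputs exist; deterministic given the inputs."""
    report = StudyReport(provenance=dict(inputs.provenance))
    report.provenance.setdefault("version", __version__)
    if config.seed is not None:
        report.provenance.setdefault("seed", config.seed)

    if inputs.quench_family:
        fits = [fit_stern_volmer(s, tau0_s=config.tau0_s) for s in inputs.quench_family]
        fits.sort(key=lambda f: f.temperature_K)
        report.quenching = fits
        if len(fits) >= 2:
            report.mechanism = classify_mechanism(fits, kq_threshold=config.kq_threshold)
        bfits = [fit_double_log(s) for s in inputs.quench_family]
        bfits.sort(key=lambda f: f.temperature_K)
        report.binding = bfits
        if len({f.temperature_K for f in bfits}) >= 2:
            report.thermodynamics = fit_vant_hoff(bfits)
            report.forces = classify_forces(
                report.thermodynamics.dH_J, report.thermodynamics.dS_J
            )
    if inputs.uv_spectra:
        report.uv_shift = analyze_uv_titration(inputs.uv_spectra, band_nm=config.uv_band_nm)
    if inputs.sync15:
        report.sync15_shift = analyze_sync_shift(inputs.sync15, delta_lambda=15)
    if inputs.sync60:
        report.sync60_shift = analyze_sync_shift(inputs.sync60, delta_lambda=60)
    if inputs.cd_apo is not None:
        report.cd_apo = cd_record(
            inputs.cd_apo, inputs.cd_protein_conc, inputs.cd_n_residues, inputs.cd_path_length_cm
        )
    if inputs.cd_complex is not None:
        report.cd_complex = cd_record(
            inputs.cd_complex,
            inputs.cd_protein_conc,
            inputs.cd_n_residues,
            inputs.cd_path_length_cm,
        )
    if inputs.displacement:
        report.site = predict_binding_site(inputs.displacement, margin_pct=config.site_margin_pct)
    if inputs.thermal_apo is not None and inputs.thermal_complex is not None:
        report.stabilization = compare_thermal(inputs.thermal_apo, inputs.thermal_complex)
    if inputs.esterase:
        report.esterase = esterase_rates(inputs.esterase)
    return report


# ---------------------------------------------------------------------------
# Manifest-driven loading
# ---------------------------------------------------------------------------


def _file_sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _ordered_spectra(manifest: ExperimentManifest, kind: SpectrumKind) -> list[Spectrum]:
    keys = sorted(manifest.files)
    return [read_spectrum(manifest.resolve(k), kind) for k in keys]


def _read_displacement_csv(path: Path, marker: Marker) -> DisplacementCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["marker_uM", "F2"]:
        raise FormatError(f"{path}: expected columns marker_uM,F2")
    conc = df["marker_uM"].to_numpy(dtype=float) * 1e-6
    f2 = df["F2"].to_numpy(dtype=float)
    order = np.argsort(conc)
    conc, f2 = conc[order], f2[order]
    if conc[0] != 0.0:
        raise ValidationError(f"{path}: a zero-marker row (F1) is required")
    return DisplacementCurve(marker, conc, float(f2[0]), f2)


def _read_thermal_csv(path: Path, label: str) -> ThermalProfile:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["temp_C", "FI343"]:
        raise FormatError(f"{path}: expected columns temp_C,FI343")
    return ThermalProfile(df["temp_C"].to_numpy(float), df["FI343"].to_numpy(float), label=label)


def _read_progress_csv(path: Path, drug_conc_M: float) -> ProgressCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["time_min", "A400"]:
        raise FormatError(f"{path}: expected columns time_min,A400")
    return ProgressCurve(drug_conc_M, df["time_min"].to_numpy(float), df["A400"].to_numpy(float))


def load_study(manifest_paths: Sequence[str | os.PathLike]) -> StudyInputs:
    """Assemble StudyInputs from a set of manifest files.

    Duplicate (assay, temperature) combinations are contradictory and
    rejected.  Provenance records the SHA-256 of every data file.
    """
    inputs = StudyInputs()
    hashes: dict[str, str] = {}
    seen: set[tuple[Assay, float]] = set()
    quench: list[TitrationSeries] = []
    for mp in manifest_paths:
        manifest = read_manifest(mp)
        key = (manifest.assay, manifest.temperature_K)
        if key in seen:
            raise ValidationError(f"duplicate manifest for assay {key[0].value} at {key[1]} K")
        seen.add(key)
        for fkey in manifest.files:
            p = manifest.resolve(fkey)
            hashes[str(p)] = _file_sha256(p)
        a = manifest.assay
        if a is Assay.QUENCH:
            quench.append(read_titration(manifest.resolve("titration"), manifest))
        elif a is Assay.UV:
            inputs.uv_spectra = _ordered_spectra(manifest, SpectrumKind.UV_VIS)
        elif a is Assay.SYNC15:
            inputs.sync15 = _ordered_spectra(manifest, SpectrumKind.SYNCHRONOUS)
        elif a is Assay.SYNC60:
            inputs.sync60 = _ordered_spectra(manifest, SpectrumKind.SYNCHRONOUS)
        elif a is Assay.CD:
            inputs.cd_apo = read_spectrum(manifest.resolve("apo"), SpectrumKind.CD)
            inputs.cd_complex = read_spectrum(manifest.resolve("complex"), SpectrumKind.CD)
            inputs.cd_protein_conc = manifest.protein_conc
            inputs.cd_n_residues = manifest.n_residues
            inputs.cd_path_length_cm = manifest.path_length_cm
        elif a is Assay.DISPLACEMENT:
            inputs.displacement = [
                _read_displacement_csv(manifest.resolve(k), Marker(k)) for k in sorted(manifest.files)
            ]
        elif a is Assay.THERMAL:
            inputs.thermal_apo = _read_thermal_csv(manifest.resolve("apo"), "apo")
            inputs.thermal_complex = _read_thermal_csv(manifest.resolve("complex"), "complex")
        elif a is Assay.ESTERASE:
            inputs.esterase = [
                _read_progress_csv(manifest.resolve(k), float(k) * 1e-6)
                for k in sorted(manifest.files, key=float)
            ]
    if quench:
        inputs.quench_family = sorted(quench, key=lambda s: s.temperature_K)
    inputs.provenance["input_hashes"] = dict(sorted(hashes.items()))
    return inputs


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------


def _q(value: float | None, units: str) -> dict | None:
    if value is None:
        return None
    return {"value": float(value), "units": units}


def _report_to_dict(r: StudyReport) -> dict:
    not_run = {"status": "not run"}

    def quench_block():
        if r.quenching is None:
            return not_run
        return {
            "status": "ok",
            "fits": [
                {
                    "temperature": _q(f.temperature_K, "K"),
                    "Ksv": _q(f.Ksv, "M^-1"),
                    "Ksv_se": _q(f.Ksv_se, "M^-1"),
                    "kq": _q(f.kq, "M^-1 s^-1"),
                    "intercept": _q(f.intercept, "dimensionless"),
                    "r_squared": _q(f.r_squared, "dimensionless"),
                    "tau0": _q(f.tau0_s, "s"),
                    "zero_slope": f.zero_slope,
                }
                for f in r.quenching
            ],
        }

    def mech_block():
        if r.mechanism is None:
            return not_run
        return {
            "status": "ok",
            "mechanism": r.mechanism.mechanism.value,
            "evidence": [
                {
                    "temperature": _q(t, "K"),
                    "Ksv": _q(k, "M^-1"),
                    "kq": _q(q, "M^-1 s^-1"),
                    "kq_above_collision_limit": a,
                }
                for t, k, q, a in r.mechanism.evidence
            ],
            "reasons": list(r.mechanism.reasons),
        }

    def binding_block():
        if r.binding is None:
            return not_run
        return {
            "status": "ok",
            "fits": [
                {
                    "temperature": _q(f.temperature_K, "K"),
                    "Kb": _q(f.Kb, "M^-1"),
                    "n": _q(f.n_stoich, "dimensionless"),
                    "r_squared": _q(f.r_squared, "dimensionless"),
                }
                for f in r.binding
            ],
        }

    def thermo_block():
        if r.thermodynamics is None:
            return not_run
        t = r.thermodynamics
        return {
            "status": "ok",
            "dH": _q(t.dH_J, "J mol^-1"),
            "dS": _q(t.dS_J, "J K^-1 mol^-1"),
            "vant_hoff_r_squared": _q(t.vant_hoff_r_squared, "dimensionless"),
            "spontaneous": t.spontaneous,
            "exothermic": t.exothermic,
            "per_temperature": [
                {
                    "temperature": _q(e.temperature_K, "K"),
                    "TdS": _q(e.TdS_J, "J mol^-1"),
                    "dG": _q(e.dG_J, "J mol^-1"),
                    "dG_vs_lnKb_residual": _q(e.dG_vs_lnKb_residual_J, "J mol^-1"),
                }
                for e in t.per_T
            ],
        }

    def forces_block():
        if r.forces is None:
            return not_run
        return {
            "status": "ok",
            "label": r.forces.label.value,
            "sign_dH": r.forces.signs[0],
            "sign_dS": r.forces.signs[1],
        }

    def shift_block(s: ShiftReport | None):
        if s is None:
            return not_run
        return {
            "status": "ok",
            "peak_positions": [_q(p, "nm") for p in s.peak_positions_nm],
            "total_shift": _q(s.total_shift_nm, "nm"),
            "direction": s.direction.value,
            "intensity_trend": s.intensity_trend.value,
            "residue": s.residue,
        }

    def cd_block(c: CDRecord | None):
        if c is None:
            return not_run
        return {
            "status": "ok",
            "theta_obs": _q(c.theta_obs_mdeg, "mdeg"),
            "mre": _q(c.mre, "deg cm^2 dmol^-1"),
            "helix": _q(c.helix_pct, "percent"),
        }

    def site_block():
        if r.site is None:
            return not_run
        return {
            "status": "ok",
            "winner": r.site.winner.value if r.site.winner else None,
            "site": r.site.site,
            "subdomain": r.site.subdomain,
            "indeterminate": r.site.indeterminate,
            "margin": _q(r.site.margin_pct, "percent"),
            "terminal_I": {m.value: _q(v, "percent") for m, v in sorted(r.site.terminal_I_pct.items(), key=lambda kv: kv[0].value)},
        }

    def stab_block():
        if r.stabilization is None:
            return not_run
        s = r.stabilization
        return {
            "status": "ok",
            "stabilized": s.stabilized,
            "Tm_apo": _q(s.Tm_apo_C, "degC"),
            "Tm_complex": _q(s.Tm_complex_C, "degC"),
            "dTm": _q(s.dTm_C, "degC"),
            "temps": [_q(t, "degC") for t in s.temps_C.tolist()],
            "ratio": [_q(v, "dimensionless") for v in s.ratio.tolist()],
        }

    def esterase_block():
        if r.esterase is None:
            return not_run
        e = r.esterase
        return {
            "status": "ok",
            "call": e.call.value,
            "monotone_decrease": e.monotone_decrease,
            "drug_conc": [_q(c, "M") for c in e.drug_conc],
            "initial_rate": [_q(v, "A400 min^-1") for v in e.initial_rate],
            "relative_activity": [_q(v, "dimensionless") for v in e.relative_activity],
        }

    return {
        "quenching": quench_block(),
        "mechanism": mech_block(),
        "binding": binding_block(),
        "thermodynamics": thermo_block(),
        "forces": forces_block(),
        "uv_shift": shift_block(r.uv_shift),
        "sync15_shift": shift_block(r.sync15_shift),
        "sync60_shift": shift_block(r.sync60_shift),
        "cd_apo": cd_block(r.cd_apo),
        "cd_complex": cd_block(r.cd_complex),
        "site": site_block(),
        "stabilization": stab_block(),
        "esterase": esterase_block(),
        "provenance": r.provenance,
    }


def save_report(report: StudyReport | Mapping, path: str | os.PathLike) -> None:
    """Write a report as canonical JSON (fixed field order, '\\n'-terminated)."""
    doc = report.to_dict() if isinstance(report, StudyReport) else dict(report)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_report(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_summary_tables(report: StudyReport, out_dir: str | os.PathLike) -> None:
    """CSV summaries of the quenching, binding and thermodynamic results.

    Constants are scaled the way binding studies tabulate them
    (Ksv x1e4 M^-1, kq x1e12 M^-1 s^-1, Kb x1e4 M^-1, energies in kJ).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if report.quenching:
        pd.DataFrame(
            {
                "temp_K": [f.temperature_K for f in report.quenching],
                "Ksv_1e4_Minv": [f.Ksv / 1e4 for f in report.quenching],
                "kq_1e12_Minv_sinv": [f.kq / 1e12 for f in report.quenching],
                "r_squared": [f.r_squared for f in report.quenching],
            }
        ).to_csv(out / "stern_volmer.csv", index=False)
    if report.binding:
        pd.DataFrame(
            {
                "temp_K": [f.temperature_K for f in report.binding],
                "Kb_1e4_Minv": [f.Kb / 1e4 for f in report.binding],
                "n": [f.n_stoich for f in report.binding],
                "r_squared": [f.r_squared for f in report.binding],
            }
        ).to_csv(out / "binding.csv", index=False)
    if report.thermodynamics:
        t = report.thermodynamics
        pd.DataFrame(
            {
                "temp_K": [e.temperature_K for e in t.per_T],
                "dH_kJ_mol": [t.dH_J / 1e3] * len(t.per_T),
                "dS_J_K_mol": [t.dS_J] * len(t.per_T),
                "TdS_kJ_mol": [e.TdS_J / 1e3 for e in t.per_T],
                "dG_kJ_mol": [e.dG_J / 1e3 for e in t.per_T],
            }
        ).to_csv(out / "thermodynamics.csv", index=False)
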