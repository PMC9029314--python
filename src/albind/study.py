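"""Assemble a complete synthetic study, in memory or on disk.

``synthetic_study_inputs`` builds every assay's data from one
GroundTruth, ready for :func:`albind.report.run_pipeline`;
``write_synthetic_study`` additionally writes the study to a directory
of CSV files and YAML manifests in the package's interchange formats, so
the file-based loaders and the CLI can be exercised end to end.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .core import (
    Assay,
    ExperimentManifest,
    write_manifest,
    write_spectrum,
    write_titration,
)
from .report import StudyInputs
from .synth import (
    GroundTruth,
    simulate_cd,
    simulate_displacement,
    simulate_esterase,
    simulate_sync_spectra,
    simulate_temperature_family,
    simulate_thermal,
    simulate_uv_titration,
)

__all__ = ["synthetic_study_inputs", "write_synthetic_study"]

def synthetic_study_inputs(
    truth: GroundTruth | None = None,
    helix_frac_complex: float = 0.4888,
    dTm_C: float = 5.0,
) -> StudyInputs:
    """Every assay's synthetic data for one ground truth.

    The apo CD helix fraction comes from ``truth.helix_frac``; the
    complex gets ``helix_frac_complex`` (a modest helix loss on binding).
    The quench family carries the van 't Hoff temperature dependence, so
    the downstream mechanism call is static and the fitted (dH, dS)
    match the injected pair.
    """
    truth = truth or GroundTruth()
    return StudyInputs(**_inputs_dict(truth, helix_frac_complex, dTm_C))


def _inputs_dict(truth: GroundTruth, helix_frac_complex: float, dTm_C: float) -> dict:
    sync_factors = (1.0, 0.9, 0.8, 0.7, 0.6)
    apo, cpx = simulate_thermal(dTm_C=dTm_C, noise_sd=0.0, seed=truth.seed)
    return dict(
        quench_family=simulate_temperature_family(truth),
        uv_spectra=simulate_uv_titration(truth),
        sync15=simulate_sync_spectra(peak_center_nm=285.0, quench_factors=sync_factors),
        sync60=simulate_sync_spectra(peak_center_nm=340.0, quench_factors=sync_factors),
        cd_apo=simulate_cd(truth.helix_frac),
        cd_complex=simulate_cd(helix_frac_complex),
        displacement=simulate_displacement(),
        thermal_apo=apo,
        thermal_complex=cpx,
        esterase=simulate_esterase(seed=truth.seed),
        provenance={"ground_truth_seed": truth.seed},
    )


def write_synthetic_study(
    truth: GroundTruth | None = None,
    out_dir: str | os.PathLike = "study",
    helix_frac_complex: float = 0.4888,
    dTm_C: float = 5.0,
) -> list[Path]:
    """Write a full synthetic study as CSVs + manifests; returns manifest paths."""
    truth = truth or GroundTruth()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifests: list[Path] = []

    def emit(manifest: ExperimentManifest, name: str) -> None:
        p = out / name
        write_manifest(manifest, p)
        manifests.append(p)

    for series in simulate_temperature_family(truth):
        t = int(round(series.temperature_K))
        fname = f"quench_{t}K.csv"
        write_titration(series, out / fname)
        emit(
            ExperimentManifest(
                assay=Assay.QUENCH, files={"titration": fname}, temperature_K=series.temperature_K
            ),
            f"quench_{t}K.yaml",
        )

    uv = simulate_uv_titration(truth)
    files = {}
    for i, spec in enumerate(uv):
        fname = f"uv_{i:02d}.csv"
        write_spectrum(spec, out / fname, value_name="A")
        files[f"{i:02d}"] = fname
    emit(ExperimentManifest(assay=Assay.UV, files=files), "uv.yaml")

    for assay, center in ((Assay.SYNC15, 285.0), (Assay.SYNC60, 340.0)):
        spectra = simulate_sync_spectra(
            peak_center_nm=center, quench_factors=(1.0, 0.9, 0.8, 0.7, 0.6)
        )
        files = {}
        for i, spec in enumerate(spectra):
            fname = f"{assay.value}_{i:02d}.csv"
            write_spectrum(spec, out / fname, value_name="F")
            files[f"{i:02d}"] = fname
        emit(ExperimentManifest(assay=assay, files=files), f"{assay.value}.yaml")

    write_spectrum(simulate_cd(truth.helix_frac), out / "cd_apo.csv", value_name="theta_mdeg")
    write_spectrum(simulate_cd(helix_frac_complex), out / "cd_complex.csv", value_name="theta_mdeg")
    emit(
        ExperimentManifest(assay=Assay.CD, files={"apo": "cd_apo.csv", "complex": "cd_complex.csv"}),
        "cd.yaml",
    )

    files = {}
    for curve in simulate_displacement():
        fname = f"displace_{curve.marker.value}.csv"
        pd.DataFrame(
            {"marker_uM": curve.marker_conc * 1e6, "F2": curve.F2}
        ).to_csv(out / fname, index=False)
        files[curve.marker.value] = fname
    emit(ExperimentManifest(assay=Assay.DISPLACEMENT, files=files), "displacement.yaml")

    apo, cpx = simulate_thermal(dTm_C=dTm_C, seed=truth.seed)
    for profile, name in ((apo, "thermal_apo.csv"), (cpx, "thermal_complex.csv")):
        pd.DataFrame({"temp_C": profile.temps_C, "FI343": profile.fi343}).to_csv(
            out / name, index=False
        )
    emit(
        ExperimentManifest(
            assay=Assay.THERMAL,
            files={"apo": "thermal_apo.csv", "complex": "thermal_complex.csv"},
            emission_nm=343.0,
        ),
        "thermal.yaml",
    )

    files = {}
    for curve in simulate_esterase(seed=truth.seed):
        key = f"{curve.drug_conc * 1e6:g}"
        fname = f"esterase_{key}uM.csv"
        pd.DataFrame({"time_min": curve.time_min, "A400": curve.a400}).to_csv(
            out / fname, index=False
        )
        files[key] = fname
    emit(ExperimentManifest(assay=Assay.ESTERASE, files=files), "esterase.yaml")

    return manifests
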