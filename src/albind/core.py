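"""Domain types, units and plain-text I/O for spectral and titration data.

All concentrations are stored in molar (M) internally.  Input CSV files
report quencher/ligand concentrations in µM, matching how binding studies
are usually tabulated; readers convert exactly (×1e-6).  Spectra are
two-column CSV (``wavelength_nm,<value>``); titrations are
``quencher_uM,F``.  Experiment manifests are small YAML files that name
the assay type, the data files and the instrument metadata every
downstream stage needs (temperature, excitation/emission wavelengths,
protein concentration, cuvette path length, residue count, fluorophore
lifetime).
"""

from __future__ import annotations

import enum
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "ValidationError",
    "SpectrumKind",
    "Assay",
    "Spectrum",
    "TitrationPoint",
    "TitrationSeries",
    "ExperimentManifest",
    "read_spectrum",
    "write_spectrum",
    "read_titration",
    "write_titration",
    "read_manifest",
    "write_manifest",
    "GAS_CONSTANT",
    "DEFAULT_TAU0_S",
    "HSA_N_RESIDUES",
]

#: Gas constant R in J mol^-1 K^-1.
GAS_CONSTANT = 8.314

#: Unquenched fluorophore lifetime assumed for biopolymers, in seconds.
DEFAULT_TAU0_S = 1e-8

#: Residue count of human serum albumin (single chain).
HSA_N_RESIDUES = 585


class FormatError(ValueError):
    """A data file does not conform to the expected layout."""


class ValidationError(ValueError):
    """In-memory data violates a domain invariant."""


class SpectrumKind(str, enum.Enum):
    UV_VIS = "uv_vis"
    FLUORESCENCE = "fluorescence"
    SYNCHRONOUS = "synchronous"
    CD = "cd"


class Assay(str, enum.Enum):
    QUENCH = "quench"
    UV = "uv"
    SYNC15 = "sync15"
    SYNC60 = "sync60"
    CD = "cd"
    DISPLACEMENT = "displacement"
    THERMAL = "thermal"
    ESTERASE = "esterase"


def _as_float_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class Spectrum:
    """A single scan: intensity (or absorbance/ellipticity) on a wavelength grid.

    The grid must be strictly increasing; UV-Vis absorbances must be
    non-negative.  Fluorescence and CD values are in instrument units
    (a.u. / millidegrees) and may take any sign for CD.
    """

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    kind: SpectrumKind

    def __post_init__(self) -> None:
        wl = _as_float_array(self.wavelength_nm, "wavelength_nm")
        inten = _as_float_array(self.intensity, "intensity")
        if wl.size != inten.size:
            raise ValidationError("wavelength and intensity lengths differ")
        if wl.size == 0:
            raise ValidationError("spectrum is empty")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelength grid must be strictly increasing")
        kind = SpectrumKind(self.kind)
        if kind is SpectrumKind.UV_VIS and np.any(inten < 0):
            raise ValidationError("UV-Vis absorbance must be non-negative")
        wl.setflags(write=False)
        inten.setflags(write=False)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "intensity", inten)
        object.__setattr__(self, "kind", kind)

    def __len__(self) -> int:
        return int(self.wavelength_nm.size)

    def value_at(self, nm: float) -> float:
        """Intensity at a wavelength, linearly interpolated within the grid."""
        if nm < self.wavelength_nm[0] or nm > self.wavelength_nm[-1]:
            raise ValidationError(f"{nm} nm lies outside the measured grid")
        return float(np.interp(nm, self.wavelength_nm, self.intensity))


@dataclass(frozen=True)
class TitrationPoint:
    """One addition step: total quencher concentration (M) and fluorescence (a.u.)."""

    quencher_conc: float
    fluorescence: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.quencher_conc) or self.quencher_conc < 0:
            raise ValidationError("quencher_conc must be finite and >= 0")
        if not math.isfinite(self.fluorescence) or self.fluorescence <= 0:
            raise ValidationError("fluorescence must be finite and > 0")


@dataclass(frozen=True)
class TitrationSeries:
    """A quenching titration at one temperature.

    Exactly one point has zero quencher concentration (its fluorescence is
    F0); concentrations are strictly increasing.
    """

    points: tuple[TitrationPoint, ...]
    temperature_K: float
    excitation_nm: float = 295.0
    emission_nm: float = 340.0
    protein_conc: float = 5e-6

    def __post_init__(self) -> None:
        pts = tuple(self.points)
        if not pts:
            raise ValidationError("titration series is empty")
        conc = np.array([p.quencher_conc for p in pts])
        n_zero = int(np.sum(conc == 0.0))
        if n_zero != 1:
            raise ValidationError(
                f"series must contain exactly one zero-concentration point, found {n_zero}"
            )
        if not np.all(np.diff(conc) > 0):
            raise ValidationError("quencher concentrations must be strictly increasing")
        if not (math.isfinite(self.temperature_K) and self.temperature_K > 0):
            raise ValidationError("temperature_K must be > 0")
        object.__setattr__(self, "points", pts)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([p.quencher_conc for p in self.points])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.fluorescence for p in self.points])

    @property
    def f0(self) -> float:
        """Fluorescence of the protein alone (the zero-concentration point)."""
        for p in self.points:
            if p.quencher_conc == 0.0:
                return p.fluorescence
        raise AssertionError("unreachable: validated series has a zero point")

    def with_intensities(self, fluorescence: Sequence[float]) -> "TitrationSeries":
        f = _as_float_array(fluorescence, "fluorescence")
        if f.size != len(self.points):
            raise ValidationError("replacement intensities length mismatch")
        pts = tuple(
            TitrationPoint(p.quencher_conc, float(v)) for p, v in zip(self.points, f)
        )
        return replace(self, points=pts)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class ExperimentManifest:
    """Names an assay, its data files and the metadata the analysis needs.

    ``tau0_s`` is the unquenched fluorophore lifetime used to turn the
    Stern–Volmer constant into a bimolecular rate constant (1e-8 s for
    biopolymers).  ``n_residues`` matters only for CD (mean-residue
    normalisation); ``path_length_cm`` for CD and UV.
    """

    assay: Assay
    files: Mapping[str, str] = field(default_factory=dict)
    temperature_K: float = 295.0
    excitation_nm: float = 295.0
    emission_nm: float = 340.0
    protein_conc: float = 5e-6
    path_length_cm: float = 1.0
    n_residues: int = HSA_N_RESIDUES
    tau0_s: float = DEFAULT_TAU0_S
    base_dir: str = "."

    def __post_init__(self) -> None:
        object.__setattr__(self, "assay", Assay(self.assay))
        if not (math.isfinite(self.tau0_s) and self.tau0_s > 0):
            raise ValidationError("tau0_s must be > 0")
        if self.temperature_K <= 0:
            raise ValidationError("temperature_K must be > 0")
        object.__setattr__(self, "files", dict(self.files))

    def resolve(self, key: str) -> Path:
        return Path(self.base_dir) / self.files[key]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_two_column_csv(path: str | os.PathLike) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected exactly two columns, got {df.shape[1]}")
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no data rows")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"{path}: column {col!r} contains non-numeric rows")
    if df.isna().any().any():
        raise FormatError(f"{path}: malformed (missing) values")
    return df


def read_spectrum(path: str | os.PathLike, kind: SpectrumKind | str) -> Spectrum:
    """Read a two-column ``wavelength_nm,<value>`` CSV into a Spectrum."""
    df = _read_two_column_csv(path)
    if df.columns[0] != "wavelength_nm":
        raise FormatError(f"{path}: first column must be 'wavelength_nm'")
    try:
        return Spectrum(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), SpectrumKind(kind))
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_spectrum(spectrum: Spectrum, path: str | os.PathLike, value_name: str = "value") -> None:
    df = pd.DataFrame(
        {"wavelength_nm": spectrum.wavelength_nm, value_name: spectrum.intensity}
    )
    # pandas' default float formatting is repr-based and round-trips exactly
    df.to_csv(path, index=False)


def read_titration(
    path: str | os.PathLike, manifest: ExperimentManifest | None = None
) -> TitrationSeries:
    """Read a ``quencher_uM,F`` CSV; concentrations converted µM -> M exactly."""
    df = _read_two_column_csv(path)
    if list(df.columns) != ["quencher_uM", "F"]:
        raise FormatError(f"{path}: expected columns quencher_uM,F, got {list(df.columns)}")
    conc_um = df["quencher_uM"].to_numpy(dtype=float)
    if np.unique(conc_um).size != conc_um.size:
        raise ValidationError(f"{path}: duplicate quencher concentrations")
    order = np.argsort(conc_um)
    conc_m = conc_um[order] * 1e-6
    f = df["F"].to_numpy(dtype=float)[order]
    points = tuple(TitrationPoint(c, v) for c, v in zip(conc_m, f))
    kwargs = {}
    if manifest is not None:
        kwargs = dict(
            temperature_K=manifest.temperature_K,
            excitation_nm=manifest.excitation_nm,
            emission_nm=manifest.emission_nm,
            protein_conc=manifest.protein_conc,
        )
    return TitrationSeries(points, **({"temperature_K": 295.0} | kwargs))


def write_titration(series: TitrationSeries, path: str | os.PathLike) -> None:
    # dividing by 1e-6 (the reader's exact conversion factor) makes
    # read_titration(write_titration(s)) bit-identical on molar values
    df = pd.DataFrame(
        {
            "quencher_uM": series.concentrations / 1e-6,
            "F": series.intensities,
        }
    )
    df.to_csv(path, index=False)


def read_manifest(path: str | os.PathLike) -> ExperimentManifest:
    """Read a YAML manifest; referenced data files must exist next to it."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "assay" not in raw:
        raise FormatError(f"{path}: manifest must be a mapping with an 'assay' key")
    files = raw.get("files", {}) or {}
    base = path.parent
    for key, rel in files.items():
        if not (base / rel).exists():
            raise ValidationError(f"{path}: referenced file {rel!r} does not exist")
    protein_conc = raw.get("protein_uM")
    kwargs = dict(
        assay=raw["assay"],
        files=files,
        base_dir=str(base),
    )
    for name in ("temperature_K", "excitation_nm", "emission_nm", "path_length_cm", "tau0_s"):
        if name in raw:
            kwargs[name] = float(raw[name])
    if protein_conc is not None:
        kwargs["protein_conc"] = float(protein_conc) * 1e-6
    if "n_residues" in raw:
        kwargs["n_residues"] = int(raw["n_residues"])
    return ExperimentManifest(**kwargs)


def write_manifest(manifest: ExperimentManifest, path: str | os.PathLike) -> None:
    doc = {
        "assay": manifest.assay.value,
        "temperature_K": manifest.temperature_K,
        "excitation_nm": manifest.excitation_nm,
        "emission_nm": manifest.emission_nm,
        "protein_uM": manifest.protein_conc * 1e6,
        "path_length_cm": manifest.path_length_cm,
        "n_residues": manifest.n_residues,
        "tau0_s": manifest.tau0_s,
        "files": dict(manifest.files),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
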