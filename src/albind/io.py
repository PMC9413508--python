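"""CSV readers/writers, analysis configuration, and run provenance.

All concentrations are stored internally in mol/L and temperatures in kelvin;
readers accept other units at the boundary via explicit arguments.  Every
reader validates the documented dialect and raises :class:`ParseError` naming
the offending column or row.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .displacement import DisplacementSeries, marker_site
from .errors import ParseError
from .lifetime import DecayCurve
from .preprocess import (
    EmissionSpectrum,
    TitrationPoint,
    TitrationSeries,
    analysis_intensities,
)
from .structure import SynchronousSeries

_CONC_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "μM": 1e-6, "nM": 1e-9}


class AnalysisConfig(BaseModel):
    """Tunable thresholds and physical defaults for the whole pipeline."""

    tau0: float = Field(1.0e-8, gt=0, description="unquenched fluorophore lifetime, s")
    kq_ceiling: float = Field(2.0e10, gt=0, description="diffusion-limited Kq, L/mol/s")
    chi2_threshold: float = Field(1.3, gt=0, description="reduced chi^2 acceptance for decay fits")
    lifetime_invariance_threshold: float = Field(
        0.05, gt=0, description="relative lifetime change treated as invariant"
    )
    displacement_threshold: float = Field(
        20.0, gt=0, description="percentage-point drop in I defining marker competition"
    )
    electrostatic_dH_ceiling: float = Field(
        1.0e4, gt=0, description="'small positive' dH ceiling for the electrostatic rule, J/mol"
    )
    ridge_tolerance: float = Field(12.0, gt=0, description="Rayleigh ridge half-width, nm")
    n_residues: int = Field(585, gt=0, description="protein residue count (HSA default)")
    protein_conc: float = Field(2e-6, gt=0, description="protein concentration, mol/L")
    path_length: float = Field(0.1, gt=0, description="CD cuvette path length, cm")
    seed: int = Field(0, ge=0, description="seed for any stochastic step")

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        return cls.model_validate_json(Path(path).read_text())

    def to_json(self, path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))


@dataclass
class RunRecord:
    """Provenance for one analysis run: config, input digests, warnings."""

    config: dict
    software_version: str = __version__
    input_digests: Dict[str, str] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)

    def add_input(self, path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.input_digests[str(path)] = digest

    def warn(self, stage: str, message: str) -> None:
        self.warnings.append(f"[{stage}] {message}")

    def as_dict(self) -> dict:
        return {
            "config": self.config,
            "software_version": self.software_version,
            "input_digests": dict(self.input_digests),
            "warnings": list(self.warnings),
        }


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    for col in columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            raise ParseError(f"{path}: non-numeric value in column {col!r}, row {bad[0]}")
        if converted.isna().any() and col not in ("A_ex", "A_em"):
            raise ParseError(f"{path}: empty cell in column {col!r}")
        df[col] = converted
    return df


def read_titration(
    path,
    conc_unit: str = "M",
    celsius: bool = False,
    protein_conc: float = 2e-6,
) -> List[TitrationSeries]:
    """Read long-format titration CSV into one series per temperature.

    Columns: temperature_K (or _C with ``celsius=True``), quencher_conc_M,
    wavelength_nm, intensity, optional A_ex / A_em.  Rows sharing a
    (temperature, quencher) pair form an emission spectrum; the analysis
    intensity is then taken at the free-protein peak wavelength.  A single row
    per pair is treated as an already-reduced intensity.
    """
    if conc_unit not in _CONC_FACTORS:
        raise ParseError(f"unknown concentration unit {conc_unit!r}")
    factor = _CONC_FACTORS[conc_unit]
    df = pd.read_csv(path)
    _require_columns(df, ["temperature_K", "quencher_conc_M", "wavelength_nm", "intensity"], path)
    numeric_cols = ["temperature_K", "quencher_conc_M", "wavelength_nm", "intensity"]
    for opt in ("A_ex", "A_em"):
        if opt in df.columns:
            numeric_cols.append(opt)
    df = _numeric(df, numeric_cols, path)

    series_list: List[TitrationSeries] = []
    for temp, tgroup in df.groupby("temperature_K", sort=True):
        temperature = float(temp) + (273.15 if celsius else 0.0)
        per_conc = []
        for conc, cgroup in tgroup.groupby("quencher_conc_M", sort=True):
            wls = cgroup["wavelength_nm"].to_numpy(dtype=float)
            if len(np.unique(wls)) != len(wls):
                raise ParseError(
                    f"{path}: duplicated (temperature, quencher_conc, wavelength) rows "
                    f"at T={temp}, [Q]={conc}"
                )
            per_conc.append((float(conc) * factor, cgroup.sort_values("wavelength_nm")))
        n_wl = {len(g) for _, g in per_conc}
        points = []
        if n_wl == {1}:
            analysis_wl = float(per_conc[0][1]["wavelength_nm"].iloc[0])
            for conc, g in per_conc:
                row = g.iloc[0]
                points.append(_point_from_row(conc, row))
        else:
            spectra = [
                EmissionSpectrum(
                    wavelengths=g["wavelength_nm"].to_numpy(dtype=float),
                    intensities=g["intensity"].to_numpy(dtype=float),
                    temperature=temperature,
                )
                for _, g in per_conc
            ]
            values, analysis_wl = analysis_intensities(spectra)
            for (conc, g), value in zip(per_conc, values):
                row = g.iloc[0]  # absorbances are per titration point, constant over wavelength
                points.append(_point_from_row(conc, row, intensity=float(value)))
        series_list.append(
            TitrationSeries(
                temperature=temperature,
                points=tuple(points),
                protein_conc=protein_conc,
                analysis_wavelength=analysis_wl,
            )
        )
    return series_list


def _point_from_row(conc: float, row, intensity: Optional[float] = None) -> TitrationPoint:
    a_ex = row.get("A_ex") if "A_ex" in row.index else None
    a_em = row.get("A_em") if "A_em" in row.index else None
    a_ex = None if a_ex is None or pd.isna(a_ex) else float(a_ex)
    a_em = None if a_em is None or pd.isna(a_em) else float(a_em)
    return TitrationPoint(
        quencher_conc=conc,
        raw_intensity=float(row["intensity"]) if intensity is None else intensity,
        absorbance_ex=a_ex,
        absorbance_em=a_em,
    )


def write_titration(series_list, path) -> None:
    """Write titration series to the long CSV dialect (one row per point)."""
    rows = []
    for series in series_list:
        for p in series.points:
            row = {
                "temperature_K": series.temperature,
                "quencher_conc_M": p.quencher_conc,
                "wavelength_nm": series.analysis_wavelength,
                "intensity": p.raw_intensity,
            }
            if p.absorbance_ex is not None:
                row["A_ex"] = p.absorbance_ex
                row["A_em"] = p.absorbance_em
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_decay(path) -> DecayCurve:
    """Read a two-column TCSPC histogram CSV (time_ns, counts)."""
    df = pd.read_csv(path)
    _require_columns(df, ["time_ns", "counts"], path)
    df = _numeric(df, ["time_ns", "counts"], path)
    return DecayCurve(
        times=df["time_ns"].to_numpy(dtype=float),
        counts=df["counts"].to_numpy(dtype=float),
    )


def write_decay(curve: DecayCurve, path) -> None:
    pd.DataFrame({"time_ns": curve.times, "counts": curve.counts}).to_csv(path, index=False)


def read_cd(path) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Read far-UV CD spectra: columns sample, wavelength_nm, ellipticity_mdeg."""
    df = pd.read_csv(path)
    _require_columns(df, ["sample", "wavelength_nm", "ellipticity_mdeg"], path)
    df = _numeric(df, ["wavelength_nm", "ellipticity_mdeg"], path)
    out = {}
    for sample, group in df.groupby("sample", sort=False):
        g = group.sort_values("wavelength_nm")
        out[str(sample)] = (
            g["wavelength_nm"].to_numpy(dtype=float),
            g["ellipticity_mdeg"].to_numpy(dtype=float),
        )
    return out


def ellipticity_at(spectrum: Tuple[np.ndarray, np.ndarray], wavelength: float = 222.0) -> float:
    """Ellipticity at the nearest measured wavelength (must lie within 2 nm)."""
    wl, mdeg = spectrum
    i = int(np.argmin(np.abs(wl - wavelength)))
    if abs(wl[i] - wavelength) > 2.0:
        raise ParseError(f"no CD measurement within 2 nm of {wavelength} nm")
    return float(mdeg[i])


def read_displacement(path, conc_unit: str = "M") -> Dict[str, DisplacementSeries]:
    """Read a displacement CSV: columns marker, marker_conc_M, intensity."""
    if conc_unit not in _CONC_FACTORS:
        raise ParseError(f"unknown concentration unit {conc_unit!r}")
    factor = _CONC_FACTORS[conc_unit]
    df = pd.read_csv(path)
    _require_columns(df, ["marker", "marker_conc_M", "intensity"], path)
    df = _numeric(df, ["marker_conc_M", "intensity"], path)
    out = {}
    for marker, group in df.groupby("marker", sort=False):
        g = group.sort_values("marker_conc_M")
        out[str(marker)] = DisplacementSeries(
            marker_name=str(marker),
            marker_site=marker_site(str(marker)),
            marker_concs=g["marker_conc_M"].to_numpy(dtype=float) * factor,
            intensities=g["intensity"].to_numpy(dtype=float),
        )
    return out


def write_displacement(series_by_marker, path) -> None:
    rows = []
    for series in series_by_marker.values():
        for c, f in zip(series.marker_concs, series.intensities):
            rows.append({"marker": series.marker_name, "marker_conc_M": c, "intensity": f})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_synchronous(path) -> Dict[float, SynchronousSeries]:
    """Read synchronous scans: columns delta_lambda_nm, quencher_conc_M,
    wavelength_nm, intensity; one series per delta-lambda."""
    df = pd.read_csv(path)
    _require_columns(
        df, ["delta_lambda_nm", "quencher_conc_M", "wavelength_nm", "intensity"], path
    )
    df = _numeric(df, ["delta_lambda_nm", "quencher_conc_M", "wavelength_nm", "intensity"], path)
    out = {}
    for dl, group in df.groupby("delta_lambda_nm", sort=True):
        concs = np.array(sorted(group["quencher_conc_M"].unique()))
        rows = []
        wl_ref = None
        for conc in concs:
            g = group[group["quencher_conc_M"] == conc].sort_values("wavelength_nm")
            wl = g["wavelength_nm"].to_numpy(dtype=float)
            if wl_ref is None:
                wl_ref = wl
            elif not np.array_equal(wl, wl_ref):
                raise ParseError(f"{path}: inconsistent wavelength grid at delta-lambda {dl}")
            rows.append(g["intensity"].to_numpy(dtype=float))
        out[float(dl)] = SynchronousSeries(
            delta_lambda=float(dl),
            wavelengths=wl_ref,
            intensity_matrix=np.vstack(rows),
            quencher_concs=concs,
        )
    return out


def read_grid3d(path) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read an excitation-emission matrix CSV.

    First column ``ex_nm`` holds excitation wavelengths; remaining column
    headers are emission wavelengths in nm.
    """
    df = pd.read_csv(path)
    if df.columns[0] != "ex_nm":
        raise ParseError(f"{path}: first column must be 'ex_nm'")
    try:
        em = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ParseError(f"{path}: emission column headers must be numeric nm: {exc}") from None
    ex = df["ex_nm"].to_numpy(dtype=float)
    if not np.all(np.diff(ex) > 0) or not np.all(np.diff(em) > 0):
        raise ParseError(f"{path}: excitation/emission axes must be strictly increasing")
    grid = df.iloc[:, 1:].to_numpy(dtype=float)
    return ex, em, grid


def write_grid3d(ex, em, grid, path) -> None:
    df = pd.DataFrame(grid, columns=[("%g" % w) for w in em])
    df.insert(0, "ex_nm", ex)
    df.to_csv(path, index=False)
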