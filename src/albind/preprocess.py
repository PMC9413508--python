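"""Raw-spectrum preprocessing: inner-filter correction and emission-peak tracking.

Fluorescence titrations of a protein with an absorbing ligand suffer from the
inner filter effect: the sample itself attenuates both the excitation beam and
the emitted light.  The standard multiplicative correction

    F_c = F_m * exp((A1 + A2) / 2)

uses the absorbance at the excitation (A1) and emission (A2) wavelengths.
This module also locates emission maxima with sub-grid resolution so that
peak drifts (red/blue shifts) along a titration can be quantified.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import AlbindWarning, InvalidInputError, NoPeakError

#: Absorbance above which the exponential inner-filter correction is dubious.
HIGH_ABSORBANCE_LIMIT = 2.0


@dataclass(frozen=True)
class EmissionSpectrum:
    """A single steady-state emission scan at fixed excitation wavelength."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    excitation_wavelength: float = 280.0
    temperature: Optional[float] = None

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or inten.ndim != 1 or wl.size != inten.size:
            raise InvalidInputError("wavelengths and intensities must be 1-D and equal length")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise InvalidInputError("wavelengths must be strictly increasing")
        if np.any(inten < 0):
            raise InvalidInputError("intensities must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", inten)


@dataclass(frozen=True)
class TitrationPoint:
    """One quencher addition: measured intensity plus optional absorbance pair.

    ``corrected_intensity`` is filled in automatically from the inner-filter
    formula when both absorbances are present, and equals the raw intensity
    otherwise.
    """

    quencher_conc: float
    raw_intensity: float
    absorbance_ex: Optional[float] = None
    absorbance_em: Optional[float] = None
    corrected_intensity: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.quencher_conc < 0:
            raise InvalidInputError("quencher concentration must be >= 0")
        if self.raw_intensity < 0:
            raise InvalidInputError("raw intensity must be >= 0")
        if self.corrected_intensity is None:
            if self.absorbance_ex is not None and self.absorbance_em is not None:
                corrected = correct_inner_filter(
                    self.raw_intensity, self.absorbance_ex, self.absorbance_em
                )
            else:
                corrected = float(self.raw_intensity)
            object.__setattr__(self, "corrected_intensity", corrected)

    @property
    def is_corrected(self) -> bool:
        return self.absorbance_ex is not None and self.absorbance_em is not None


@dataclass(frozen=True)
class TitrationSeries:
    """Ordered titration at one temperature; the first point ([Q] = 0) defines F0."""

    temperature: float
    points: tuple
    protein_conc: float = 2e-6
    analysis_wavelength: float = 337.0

    def __post_init__(self):
        pts = tuple(self.points)
        if len(pts) == 0:
            raise InvalidInputError("a titration series needs at least one point")
        if pts[0].quencher_conc != 0.0:
            raise InvalidInputError("the first titration point must have [Q] = 0 (defines F0)")
        concs = [p.quencher_conc for p in pts]
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise InvalidInputError("quencher concentrations must be strictly increasing")
        object.__setattr__(self, "points", pts)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([p.quencher_conc for p in self.points], dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        """Analysis intensities (inner-filter corrected where possible)."""
        return np.array([p.corrected_intensity for p in self.points], dtype=float)

    @property
    def f0(self) -> float:
        return float(self.points[0].corrected_intensity)

    @property
    def is_corrected(self) -> bool:
        return all(p.is_corrected for p in self.points)


def correct_inner_filter(raw_intensity: float, absorbance_ex: float, absorbance_em: float) -> float:
    """Inner-filter corrected intensity F_c = F_m * exp((A1 + A2)/2)."""
    if raw_intensity < 0:
        raise InvalidInputError("raw intensity must be >= 0")
    a1 = float(absorbance_ex)
    a2 = float(absorbance_em)
    if not (math.isfinite(a1) and math.isfinite(a2)):
        raise InvalidInputError("absorbances must be finite")
    if a1 > HIGH_ABSORBANCE_LIMIT or a2 > HIGH_ABSORBANCE_LIMIT:
        warnings.warn(
            "absorbance > %.1f: inner-filter correction is unreliable at high optical density"
            % HIGH_ABSORBANCE_LIMIT,
            AlbindWarning,
            stacklevel=2,
        )
    return float(raw_intensity) * math.exp((a1 + a2) / 2.0)


def _parabolic_vertex(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Vertex of the parabola through three points; falls back to the middle point."""
    a, b, c = np.polyfit(x, y, 2)
    if a >= 0:  # degenerate (flat or upward) — no refinement possible
        return float(x[1]), float(y[1])
    xv = -b / (2.0 * a)
    yv = c - b * b / (4.0 * a)
    return float(xv), float(yv)


def _peak_candidates(intensities: np.ndarray) -> list[int]:
    """Interior indices that are true local maxima (plateau-aware).

    A candidate must be >= both neighbours and have some strictly smaller
    value on each side, so monotone ramps and flat traces yield nothing while
    a two-sample plateau at a peak top still counts.
    """
    y = intensities
    candidates = []
    for i in range(1, y.size - 1):
        if y[i] >= y[i - 1] and y[i] >= y[i + 1]:
            if (y[:i] < y[i]).any() and (y[i + 1 :] < y[i]).any():
                candidates.append(i)
    return candidates


def refine_peak(wavelengths: np.ndarray, intensities: np.ndarray) -> tuple[float, float]:
    """Locate the dominant interior maximum with 3-point parabolic refinement.

    Returns (peak wavelength, peak intensity).  Ties between equally tall
    maxima are broken toward the longer wavelength.  Raises
    :class:`NoPeakError` for monotone or flat traces.
    """
    wl = np.asarray(wavelengths, dtype=float)
    y = np.asarray(intensities, dtype=float)
    candidates = _peak_candidates(y)
    if not candidates:
        raise NoPeakError("no interior maximum (monotone or flat trace)")
    best = max(candidates, key=lambda i: (y[i], wl[i]))
    return _parabolic_vertex(wl[best - 1 : best + 2], y[best - 1 : best + 2])


def find_emission_peak(spectrum: EmissionSpectrum) -> float:
    """Peak emission wavelength (nm) of a spectrum, at sub-grid resolution."""
    if spectrum.wavelengths.size < 5:
        raise InvalidInputError("at least 5 samples are required to locate a peak")
    wavelength, _ = refine_peak(spectrum.wavelengths, spectrum.intensities)
    return wavelength


def peak_shift(spectra: Sequence[EmissionSpectrum]) -> float:
    """Signed emission-peak shift (nm) between the first and last spectrum.

    Positive values are redshifts.  For a protein titration ordered by
    quencher concentration this is the total peak drift over the titration.
    """
    if len(spectra) < 2:
        raise InvalidInputError("peak_shift needs at least two spectra")
    return find_emission_peak(spectra[-1]) - find_emission_peak(spectra[0])


def analysis_intensities(
    spectra: Sequence[EmissionSpectrum], analysis_wavelength: Optional[float] = None
) -> tuple[np.ndarray, float]:
    """Intensity of each spectrum at a fixed analysis wavelength.

    The analysis wavelength defaults to the emission peak of the *first*
    spectrum (the free protein): quenching fits read every titration point at
    the same wavelength even though the peak itself drifts.  Intensities are
    linearly interpolated onto that wavelength.
    """
    if not spectra:
        raise InvalidInputError("no spectra given")
    if analysis_wavelength is None:
        analysis_wavelength = find_emission_peak(spectra[0])
    values = np.array(
        [float(np.interp(analysis_wavelength, s.wavelengths, s.intensities)) for s in spectra]
    )
    return values, float(analysis_wavelength)
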