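"""Protein-conformation readouts: CD helix content, synchronous and 3D fluorescence.

Circular dichroism at 222 nm is converted to mean residue ellipticity

    MRE222 = theta_222(mdeg) / (10 * Cp * n * l)

(Cp molar protein concentration, n residue count — 585 for human serum
albumin, l path length in cm) and then to an alpha-helix percentage via the
empirical linear calibration

    helix(%) = (-MRE222 - 2340) / 30300 * 100.

Synchronous scans at a fixed excitation/emission offset (delta-lambda 15 nm
for tyrosine, 60 nm for tryptophan) report microenvironment polarity through
peak shifts.  Excitation-emission matrices are searched for fluorophore peaks
after masking the first-order (em = ex) and second-order (em = 2 ex) Rayleigh
scattering ridges.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .errors import InvalidInputError, NoPeakError
from .preprocess import refine_peak

#: Residues in human serum albumin.
HSA_N_RESIDUES = 585

#: Default half-width (nm) of the masked Rayleigh scattering ridges.
DEFAULT_RIDGE_TOLERANCE = 12.0

_HELIX_OFFSET = 2340.0
_HELIX_SLOPE = 30300.0


class PeakLabel(str, enum.Enum):
    PEAK_I = "peak_I"
    PEAK_II = "peak_II"
    RAYLEIGH_1 = "rayleigh_1"
    RAYLEIGH_2 = "rayleigh_2"


class HelixPercent(NamedTuple):
    value: float  # percent, clamped to [0, 100]
    clamped: bool


@dataclass(frozen=True)
class CDSample:
    """One CD measurement reduced to the 222 nm ellipticity and derived quantities."""

    ellipticity_222: float  # mdeg
    protein_conc: float  # mol/L
    n_residues: int = HSA_N_RESIDUES
    path_length: float = 0.1  # cm
    mre_222: float = None  # type: ignore[assignment]
    helix_fraction: HelixPercent = None  # type: ignore[assignment]

    def __post_init__(self):
        mre = mre_222(self.ellipticity_222, self.protein_conc, self.n_residues, self.path_length)
        object.__setattr__(self, "mre_222", mre)
        object.__setattr__(self, "helix_fraction", helix_percent(mre))


@dataclass(frozen=True)
class SynchronousSeries:
    """Synchronous scans over a titration at fixed delta-lambda (15 or 60 nm)."""

    delta_lambda: float
    wavelengths: np.ndarray  # excitation axis, nm
    intensity_matrix: np.ndarray  # one row per titration point
    quencher_concs: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.delta_lambda not in (15.0, 60.0, 15, 60):
            raise InvalidInputError("delta_lambda must be 15 or 60 nm")
        wl = np.asarray(self.wavelengths, dtype=float)
        mat = np.atleast_2d(np.asarray(self.intensity_matrix, dtype=float))
        if mat.shape[1] != wl.size:
            raise InvalidInputError("intensity matrix columns must match the wavelength axis")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensity_matrix", mat)


@dataclass(frozen=True)
class Peak3D:
    label: PeakLabel
    ex_wavelength: float
    em_wavelength: float
    stokes_shift: float  # em - ex, nm
    intensity: float


def mre_222(
    ellipticity_222: float, protein_conc: float, n_residues: int, path_length: float
) -> float:
    """Mean residue ellipticity at 222 nm (deg cm^2 dmol^-1)."""
    if protein_conc <= 0 or n_residues <= 0 or path_length <= 0:
        raise InvalidInputError("protein_conc, n_residues and path_length must be positive")
    return ellipticity_222 / (10.0 * protein_conc * n_residues * path_length)


def helix_percent(mre222: float) -> HelixPercent:
    """Alpha-helix content (%) from MRE222; clamped to [0, 100] with a flag."""
    if not np.isfinite(mre222):
        raise InvalidInputError("MRE222 must be finite")
    raw = (-mre222 - _HELIX_OFFSET) / _HELIX_SLOPE * 100.0
    clamped = raw < -1e-9 or raw > 100.0 + 1e-9  # tolerate round-off at the boundaries
    return HelixPercent(min(max(raw, 0.0), 100.0), clamped)


def sync_peak_shift(series: SynchronousSeries) -> Tuple[float, float]:
    """(signed peak shift in nm, fractional intensity change) first -> last scan."""
    if series.intensity_matrix.shape[0] < 2:
        raise InvalidInputError("need at least two synchronous scans")
    wl = series.wavelengths
    x_first, i_first = refine_peak(wl, series.intensity_matrix[0])
    x_last, i_last = refine_peak(wl, series.intensity_matrix[-1])
    return x_last - x_first, (i_last - i_first) / i_first


def _local_maxima_mask(grid: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Cells that are >= all 8-neighbours (strictly > at least one) and sit
    fully inside the unmasked region — a maximum hugging a masked ridge edge
    is ridge spill-over, not a fluorophore peak."""
    n_ex, n_em = grid.shape
    lo_pad = np.full((n_ex + 2, n_em + 2), -np.inf)  # out-of-grid never disqualifies
    lo_pad[1:-1, 1:-1] = grid
    hi_pad = np.full((n_ex + 2, n_em + 2), np.inf)  # ...and never counts as "smaller"
    hi_pad[1:-1, 1:-1] = grid
    valid_padded = np.ones((n_ex + 2, n_em + 2), dtype=bool)
    valid_padded[1:-1, 1:-1] = valid
    center = grid
    ge_all = np.ones_like(grid, dtype=bool)
    gt_any = np.zeros_like(grid, dtype=bool)
    interior = valid.copy()
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            ge_all &= center >= lo_pad[1 + di : 1 + di + n_ex, 1 + dj : 1 + dj + n_em]
            gt_any |= center > hi_pad[1 + di : 1 + di + n_ex, 1 + dj : 1 + dj + n_em]
            interior &= valid_padded[1 + di : 1 + di + n_ex, 1 + dj : 1 + dj + n_em]
    return interior & ge_all & gt_any


def extract_3d_peaks(
    excitation: Sequence[float],
    emission: Sequence[float],
    grid: np.ndarray,
    ridge_tolerance: float = DEFAULT_RIDGE_TOLERANCE,
) -> Tuple[Peak3D, ...]:
    """Identify fluorophore and scattering peaks in an excitation-emission matrix.

    The first-order (|em - ex| <= tol) and second-order (|em - 2 ex| <= tol)
    Rayleigh ridges are masked out; among the remaining local maxima, the one
    nearest 280 nm excitation is labelled peak I (aromatic residues) and the
    one nearest 230 nm is peak II (peptide backbone).  The maxima of the two
    ridges themselves are reported as rayleigh_1 / rayleigh_2 when present.
    """
    ex = np.asarray(excitation, dtype=float)
    em = np.asarray(emission, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.shape != (ex.size, em.size):
        raise InvalidInputError("grid shape must be (n_excitation, n_emission)")
    if ex.size < 3:
        raise InvalidInputError("need at least 3 excitation rows")

    exg, emg = np.meshgrid(ex, em, indexing="ij")
    ridge1 = np.abs(emg - exg) <= ridge_tolerance
    ridge2 = np.abs(emg - 2.0 * exg) <= ridge_tolerance
    valid = ~(ridge1 | ridge2)
    if not valid.any():
        raise NoPeakError("every grid cell lies on a scattering ridge")

    maxima = np.argwhere(_local_maxima_mask(grid, valid))
    if maxima.size == 0:
        raise NoPeakError("no local maximum outside the scattering ridges")

    peaks = []
    used = set()
    for label, target_ex in ((PeakLabel.PEAK_I, 280.0), (PeakLabel.PEAK_II, 230.0)):
        ranked = sorted(
            (tuple(m) for m in maxima if tuple(m) not in used),
            key=lambda m: (abs(ex[m[0]] - target_ex), -grid[m[0], m[1]]),
        )
        if not ranked:
            continue
        i, j = ranked[0]
        used.add((i, j))
        peaks.append(
            Peak3D(label, float(ex[i]), float(em[j]), float(em[j] - ex[i]),
                   float(grid[i, j]))
        )
    for label, ridge in ((PeakLabel.RAYLEIGH_1, ridge1), (PeakLabel.RAYLEIGH_2, ridge2)):
        if ridge.any():
            masked = np.where(ridge, grid, -np.inf)
            i, j = np.unravel_index(int(np.argmax(masked)), grid.shape)
            if np.isfinite(masked[i, j]) and masked[i, j] > 0:
                peaks.append(
                    Peak3D(label, float(ex[i]), float(em[j]), float(em[j] - ex[i]),
                           float(grid[i, j]))
                )
    return tuple(peaks)
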