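"""Instrument-like synthetic data with known ground truth.

No raw spectra accompany the study conditions this package targets, so every
analysis stage is exercised against generated data whose generating
parameters are known exactly.  The default :class:`GroundTruth` mirrors a
typical drug–albumin titration: 2 uM protein, quencher 0–9 uM in 7 steps,
temperatures 298/304/310 K, an association constant of 4.09e5 M^-1 at 298 K
with n = 1.14 apparent sites, binding enthalpy -118.75 kJ/mol, a 337 nm
emission peak redshifting by 12 nm over the titration, a tri-exponential
5.4907 ns free lifetime, and 53.94% alpha-helix content.

Titration intensities follow the binding isotherm

    F = F0 / (1 + Ka(T) * [Q]**n),

with Ka(T) anchored to (Ka_ref, T_ref) and propagated through the Van 't
Hoff relation; the entropy is derived from (Ka_ref, T_ref, delta_H) so the
thermodynamic triple is exactly self-consistent.  Fluorescence noise is
multiplicative Gaussian; photon counts are Poisson.  All generators are
deterministic given (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .binding_thermo import GAS_CONSTANT
from .displacement import DisplacementSeries, marker_site
from .errors import InvalidInputError
from .lifetime import DecayCurve
from .preprocess import EmissionSpectrum, TitrationPoint, TitrationSeries
from .structure import SynchronousSeries

#: Default titration grid: 0–9 uM quencher in 7 steps.
DEFAULT_CONCS = tuple(np.linspace(0.0, 9e-6, 7))

#: Default temperatures (K).
DEFAULT_TEMPERATURES = (298.0, 304.0, 310.0)

# Tri-exponential components calibrated so the amplitude-weighted mean is
# 5.4907 ns with lifetimes 0.8 / 3.2 / 6.8 ns.
_ALPHA2 = (6.2 - 5.4907) / 3.6
DEFAULT_LIFETIMES = (0.8, 3.2, 6.8)
DEFAULT_AMPLITUDES = (0.1, _ALPHA2, 0.9 - _ALPHA2)

_HELIX_OFFSET = 2340.0
_HELIX_SLOPE = 30300.0


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters for the full synthetic study.

    ``delta_S`` is derived from (Ka_ref, T_ref, delta_H) when omitted, which
    makes the Van 't Hoff relation hold exactly at T_ref; supplying an
    inconsistent triple raises.
    """

    Ka_ref: float = 4.09e5  # L/mol at T_ref
    T_ref: float = 298.0  # K
    n_sites: float = 1.14
    delta_H: float = -118750.0  # J/mol
    delta_S: Optional[float] = None  # J/mol/K, derived when None
    F0: float = 1000.0  # a.u.
    protein_conc: float = 2e-6  # mol/L
    peak_free: float = 337.0  # nm
    peak_shift_total: float = 12.0  # nm (redshift over the titration)
    emission_sigma: float = 25.0  # nm, Gaussian band width
    lifetimes: Tuple[float, ...] = DEFAULT_LIFETIMES  # ns
    amplitudes: Tuple[float, ...] = DEFAULT_AMPLITUDES
    helix_fraction: float = 53.94  # percent, free protein
    helix_fraction_bound: float = 51.98  # percent, drug-saturated
    noise_sd: float = 0.0  # fractional multiplicative noise on intensities
    seed: int = 0

    def __post_init__(self):
        if self.Ka_ref <= 0 or self.T_ref <= 0 or self.n_sites <= 0 or self.F0 <= 0:
            raise InvalidInputError("Ka_ref, T_ref, n_sites and F0 must be positive")
        derived = GAS_CONSTANT * math.log(self.Ka_ref) + self.delta_H / self.T_ref
        if self.delta_S is None:
            object.__setattr__(self, "delta_S", derived)
        else:
            implied = math.exp(-self.delta_H / (GAS_CONSTANT * self.T_ref)
                               + self.delta_S / GAS_CONSTANT)
            if abs(implied - self.Ka_ref) > 1e-9 * self.Ka_ref:
                raise InvalidInputError(
                    "inconsistent (Ka_ref, delta_H, delta_S): Van 't Hoff gives "
                    f"Ka({self.T_ref:g} K) = {implied:.6g}, expected {self.Ka_ref:.6g}"
                )

    def ka_at(self, temperature: float) -> float:
        """Association constant at a temperature via the Van 't Hoff relation."""
        if temperature <= 0:
            raise InvalidInputError("temperature must be positive")
        return math.exp(
            -self.delta_H / (GAS_CONSTANT * temperature) + self.delta_S / GAS_CONSTANT
        )

    def ksv_derived(self, temperature: float, concs: Sequence[float] = DEFAULT_CONCS) -> float:
        """Effective Stern–Volmer slope of the noiseless isotherm on a grid.

        The generating model is the n-site binding isotherm, so F0/F is linear
        in [Q] only when n = 1; this is the slope a classical Stern–Volmer
        regression reports on the noiseless curve.
        """
        from ._regression import ols

        q = np.asarray(concs, dtype=float)
        f = self.F0 / (1.0 + self.ka_at(temperature) * np.power(q, self.n_sites,
                       where=q > 0, out=np.zeros_like(q)))
        f[q == 0] = self.F0
        return ols(q, self.F0 / f).slope


@dataclass(frozen=True)
class TitrationBundle:
    """Generated titrations (and optionally full spectra) keyed by temperature."""

    series_by_T: Dict[float, TitrationSeries]
    spectra_by_T: Optional[Dict[float, Tuple[EmissionSpectrum, ...]]] = None


def generate_titration(
    truth: GroundTruth,
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES,
    concs: Sequence[float] = DEFAULT_CONCS,
    with_spectra: bool = False,
    seed: Optional[int] = None,
) -> TitrationBundle:
    """Titration intensities (and optional drifting emission spectra) per temperature."""
    q = np.asarray(concs, dtype=float)
    if q.size < 2 or q[0] != 0.0 or not np.all(np.diff(q) > 0):
        raise InvalidInputError("concs must start at 0 and be strictly increasing")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    series_by_t: Dict[float, TitrationSeries] = {}
    spectra_by_t: Dict[float, Tuple[EmissionSpectrum, ...]] = {}
    wl = np.arange(300.0, 551.0, 1.0)
    for temp in temperatures:
        ka = truth.ka_at(temp)
        with np.errstate(divide="ignore"):
            denom = 1.0 + ka * np.where(q > 0, q, 0.0) ** truth.n_sites
        denom[q == 0] = 1.0
        f = truth.F0 / denom
        if truth.noise_sd > 0:
            f = f * (1.0 + truth.noise_sd * rng.standard_normal(f.size))
            f = np.maximum(f, 1e-9 * truth.F0)
        points = tuple(
            TitrationPoint(quencher_conc=float(c), raw_intensity=float(v))
            for c, v in zip(q, f)
        )
        series_by_t[float(temp)] = TitrationSeries(
            temperature=float(temp),
            points=points,
            protein_conc=truth.protein_conc,
            analysis_wavelength=truth.peak_free,
        )
        if with_spectra:
            spectra = []
            for i, v in enumerate(f):
                center = truth.peak_free + truth.peak_shift_total * i / (q.size - 1)
                inten = v * np.exp(-0.5 * ((wl - center) / truth.emission_sigma) ** 2)
                spectra.append(EmissionSpectrum(wavelengths=wl, intensities=inten,
                                                temperature=float(temp)))
            spectra_by_t[float(temp)] = tuple(spectra)
    return TitrationBundle(series_by_t, spectra_by_t if with_spectra else None)


def generate_decay(
    lifetimes: Sequence[float] = DEFAULT_LIFETIMES,
    amplitudes: Sequence[float] = DEFAULT_AMPLITUDES,
    peak_counts: float = 1e4,
    channel_width: float = 0.05,  # ns
    n_channels: int = 4096,
    seed: int = 0,
    sample: bool = True,
    quencher_conc: float = 0.0,
) -> DecayCurve:
    """TCSPC histogram with expected counts peak_counts * sum(alpha_i exp(-t/tau_i)).

    With ``sample=True`` the observed counts are Poisson draws from the
    expectation; otherwise the noiseless expectation is returned.
    """
    taus = np.asarray(lifetimes, dtype=float)
    alphas = np.asarray(amplitudes, dtype=float)
    if taus.shape != alphas.shape or (taus <= 0).any() or (alphas < 0).any():
        raise InvalidInputError("lifetimes/amplitudes must be positive, equal length")
    if abs(alphas.sum() - 1.0) > 1e-6:
        raise InvalidInputError("amplitudes must sum to 1 within 1e-6")
    t = np.arange(n_channels) * channel_width
    expected = peak_counts * (alphas[None, :] * np.exp(-t[:, None] / taus[None, :])).sum(axis=1)
    if sample:
        counts = np.random.default_rng(seed).poisson(expected).astype(float)
    else:
        counts = expected
    return DecayCurve(times=t, counts=counts, quencher_conc=quencher_conc)


def generate_displacement(
    competing: bool,
    drop_fraction: float = 0.45,
    n_points: int = 7,
    marker: str = "warfarin",
    f1: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    max_conc: float = 9e-6,
) -> DisplacementSeries:
    """Marker titration: I declines linearly to 100*(1 - drop_fraction) if competing."""
    if not 0.0 <= drop_fraction < 1.0:
        raise InvalidInputError("drop_fraction must be in [0, 1)")
    concs = np.linspace(0.0, max_conc, n_points)
    frac = np.linspace(0.0, drop_fraction if competing else 0.0, n_points)
    intensities = f1 * (1.0 - frac)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensities = intensities * (1.0 + noise_sd * np.r_[0.0, rng.standard_normal(n_points - 1)])
    return DisplacementSeries(
        marker_name=marker,
        marker_site=marker_site(marker),
        marker_concs=concs,
        intensities=intensities,
    )


def generate_cd(
    helix_fraction: float,
    protein_conc: float = 2e-6,
    n_residues: int = 585,
    path_length: float = 0.1,
) -> float:
    """Ellipticity at 222 nm (mdeg) whose analysis returns the given helix content.

    Exact inverse of the MRE and helix calibration formulas:
    ellipticity = (-(helix/100 * 30300) - 2340) * 10 * Cp * n * l.
    """
    if not 0.0 <= helix_fraction <= 100.0:
        raise InvalidInputError("helix_fraction must lie in [0, 100]")
    mre = -(helix_fraction / 100.0 * _HELIX_SLOPE) - _HELIX_OFFSET
    return mre * 10.0 * protein_conc * n_residues * path_length


def generate_synchronous(
    delta_lambda: float,
    peak_start: float,
    peak_end: float,
    n_scans: int = 5,
    intensity_drop_fraction: float = 0.4,
    peak_intensity: float = 500.0,
    sigma: float = 8.0,
    wavelengths: Optional[np.ndarray] = None,
) -> SynchronousSeries:
    """Synchronous-scan stack with a linearly drifting, linearly quenched peak."""
    if wavelengths is None:
        wavelengths = np.arange(240.0, 321.0, 1.0)
    wl = np.asarray(wavelengths, dtype=float)
    centers = np.linspace(peak_start, peak_end, n_scans)
    heights = peak_intensity * np.linspace(1.0, 1.0 - intensity_drop_fraction, n_scans)
    mat = heights[:, None] * np.exp(-0.5 * ((wl[None, :] - centers[:, None]) / sigma) ** 2)
    return SynchronousSeries(delta_lambda=float(delta_lambda), wavelengths=wl,
                             intensity_matrix=mat)


def generate_grid3d(
    peak_i: Tuple[float, float, float] = (280.0, 345.0, 500.0),
    peak_ii: Tuple[float, float, float] = (230.0, 335.0, 300.0),
    rayleigh_intensity: float = 800.0,
    second_order_intensity: float = 200.0,
    ex: Optional[np.ndarray] = None,
    em: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Excitation-emission matrix with two fluorophore peaks plus Rayleigh ridges.

    Each peak is (ex_center, em_center, intensity); ridge signals run along
    em = ex and em = 2 ex with a narrow Gaussian cross-section.
    """
    if ex is None:
        ex = np.arange(200.0, 401.0, 10.0)
    if em is None:
        em = np.arange(200.0, 501.0, 5.0)
    ex = np.asarray(ex, dtype=float)
    em = np.asarray(em, dtype=float)
    exg, emg = np.meshgrid(ex, em, indexing="ij")
    grid = np.zeros_like(exg)
    for cx, cm, amp in (peak_i, peak_ii):
        grid += amp * np.exp(-0.5 * (((exg - cx) / 12.0) ** 2 + ((emg - cm) / 18.0) ** 2))
    grid += rayleigh_intensity * np.exp(-0.5 * ((emg - exg) / 4.0) ** 2)
    grid += second_order_intensity * np.exp(-0.5 * ((emg - 2.0 * exg) / 4.0) ** 2)
    return ex, em, grid
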