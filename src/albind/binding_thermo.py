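"""Binding constants, stoichiometry, and Van 't Hoff thermodynamics.

For a static quenching process, the double-logarithmic (modified
Stern–Volmer) form

    log10((F0 - F) / F) = n * log10([Q]) + log10(Ka)

gives the association constant Ka (intercept) and the apparent number of
binding sites n (slope).  Fitting ln Ka against 1/T (Van 't Hoff),

    ln Ka = -dH / (R T) + dS / R,

yields the binding enthalpy and entropy, from which the Gibbs energy follows
as dG = dH - T dS.  The signs of (dH, dS) map onto the dominant noncovalent
force class after Ross and Subramanian: both negative -> van der Waals plus
hydrogen bonding; both positive -> hydrophobic; positive dS with negative (or
near-zero) dH -> electrostatic.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np

from ._regression import ols
from .errors import InsufficientDataError, InvalidInputError, UnclassifiableError
from .preprocess import TitrationSeries

#: Gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314

#: Default ceiling on "small positive" dH for the electrostatic rule, J/mol.
DEFAULT_ELECTROSTATIC_DH_CEILING = 1.0e4


class ForceLabel(str, enum.Enum):
    VDW_HBOND = "vdw_hbond"
    HYDROPHOBIC = "hydrophobic"
    ELECTROSTATIC = "electrostatic"


@dataclass(frozen=True)
class BindingFit:
    """Double-log fit at one temperature: Ka = 10^intercept, n = slope."""

    temperature: float
    Ka: float
    n_sites: float
    r_squared: float
    n_points: int = 0

    def __post_init__(self):
        if self.Ka <= 0:
            raise InvalidInputError("Ka must be positive")
        if self.n_sites <= 0:
            raise InvalidInputError("n_sites must be positive")


@dataclass(frozen=True)
class VantHoffFit:
    delta_H: float  # J/mol
    delta_S: float  # J/mol/K
    r_squared: float


@dataclass(frozen=True)
class ThermoResult:
    """Joint thermodynamic summary across temperatures.

    ``delta_G_by_T`` follows the Gibbs relation dG = dH - T*dS exactly;
    ``delta_G_rt_lnka_by_T`` carries the -RT ln Ka cross-check, which differs
    only through scatter of the individual Ka values about the Van 't Hoff
    line.
    """

    delta_H: float
    delta_S: float
    vant_hoff_r_squared: float
    delta_G_by_T: Dict[float, float]
    delta_G_rt_lnka_by_T: Dict[float, float]
    force_label: ForceLabel
    gas_constant: float = GAS_CONSTANT


def fit_double_log(series: TitrationSeries) -> BindingFit:
    """Fit the double-logarithmic binding isotherm for one temperature.

    The [Q] = 0 point defines F0 and is excluded from the regression.
    """
    q = series.concentrations
    f = series.intensities
    f0 = series.f0
    mask = q > 0
    q, f = q[mask], f[mask]
    if q.size < 3:
        raise InsufficientDataError("double-log fit needs at least 3 points with [Q] > 0")
    if (f <= 0).any():
        raise InvalidInputError("intensities must be positive")
    if (f >= f0).any():
        raise InvalidInputError("no quenching: F >= F0 at some [Q] > 0")
    x = np.log10(q)
    y = np.log10((f0 - f) / f)
    slope, intercept, r2 = ols(x, y)
    return BindingFit(
        temperature=float(series.temperature),
        Ka=10.0 ** intercept,
        n_sites=slope,
        r_squared=r2,
        n_points=int(q.size),
    )


def fit_vant_hoff(binding_fits: Sequence[BindingFit]) -> VantHoffFit:
    """Linear Van 't Hoff fit of ln Ka on 1/T: dH = -R*slope, dS = R*intercept."""
    if not binding_fits:
        raise InsufficientDataError("no binding fits given")
    by_temp: Dict[float, float] = {}
    for bf in binding_fits:
        if bf.temperature <= 0:
            raise InvalidInputError("temperatures must be positive (kelvin)")
        if bf.temperature in by_temp and not math.isclose(
            by_temp[bf.temperature], bf.Ka, rel_tol=1e-12
        ):
            raise InvalidInputError(
                "duplicate temperature %.6g K with conflicting Ka values" % bf.temperature
            )
        by_temp[bf.temperature] = bf.Ka
    if len(by_temp) < 2:
        raise InsufficientDataError("Van 't Hoff fit needs at least 2 distinct temperatures")
    temps = np.array(sorted(by_temp), dtype=float)
    ln_ka = np.log([by_temp[t] for t in temps])
    slope, intercept, r2 = ols(1.0 / temps, ln_ka)
    return VantHoffFit(
        delta_H=-GAS_CONSTANT * slope,
        delta_S=GAS_CONSTANT * intercept,
        r_squared=r2,
    )


def gibbs(delta_H: float, delta_S: float, temperature: float) -> float:
    """Gibbs free energy change dG = dH - T*dS (J/mol)."""
    if temperature <= 0:
        raise InvalidInputError("temperature must be positive (kelvin)")
    return delta_H - temperature * delta_S


def classify_forces(
    delta_H: float,
    delta_S: float,
    electrostatic_dH_ceiling: float = DEFAULT_ELECTROSTATIC_DH_CEILING,
) -> ForceLabel:
    """Sign-based Ross–Subramanian force classification.

    Rules are applied in order: (dH<0, dS<0) -> van der Waals / hydrogen bond;
    (dH>0, dS>0) -> hydrophobic; dS>0 with dH negative or below a small
    positive ceiling -> electrostatic.  (dH>0, dS<0) lies outside the
    taxonomy and raises :class:`UnclassifiableError`.
    """
    if not (math.isfinite(delta_H) and math.isfinite(delta_S)):
        raise InvalidInputError("delta_H and delta_S must be finite")
    if delta_H < 0 and delta_S < 0:
        return ForceLabel.VDW_HBOND
    if delta_H > 0 and delta_S > 0:
        return ForceLabel.HYDROPHOBIC
    if delta_S > 0 and delta_H < electrostatic_dH_ceiling:
        return ForceLabel.ELECTROSTATIC
    raise UnclassifiableError(
        "thermodynamic signs outside the Ross–Subramanian taxonomy",
        diagnostics={"delta_H": delta_H, "delta_S": delta_S},
    )


def analyze_thermodynamics(
    binding_fits: Sequence[BindingFit],
    electrostatic_dH_ceiling: float = DEFAULT_ELECTROSTATIC_DH_CEILING,
) -> ThermoResult:
    """Van 't Hoff fit, Gibbs energies at each fitted temperature, force class."""
    vh = fit_vant_hoff(binding_fits)
    temps = sorted({bf.temperature for bf in binding_fits})
    ka_by_t = {bf.temperature: bf.Ka for bf in binding_fits}
    return ThermoResult(
        delta_H=vh.delta_H,
        delta_S=vh.delta_S,
        vant_hoff_r_squared=vh.r_squared,
        delta_G_by_T={t: gibbs(vh.delta_H, vh.delta_S, t) for t in temps},
        delta_G_rt_lnka_by_T={
            t: -GAS_CONSTANT * t * math.log(ka_by_t[t]) for t in temps
        },
        force_label=classify_forces(vh.delta_H, vh.delta_S, electrostatic_dH_ceiling),
    )
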