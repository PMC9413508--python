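"""Stern–Volmer quenching analysis and mechanism classification.

The classical Stern–Volmer relation

    F0 / F = 1 + Kq * tau0 * [Q] = 1 + Ksv * [Q]

is fitted per temperature by ordinary least squares of F0/F on [Q] with a
*free* intercept; a fitted intercept far from 1 is reported as a diagnostic
warning rather than forced away.  The bimolecular quenching rate coefficient
Kq = Ksv / tau0 is compared against the diffusion-limited collisional ceiling
(~2e10 L mol^-1 s^-1): values far above it are incompatible with purely
dynamic (collisional) quenching and point to ground-state complex formation.

Three independent lines of evidence vote on the mechanism:

1. temperature trend of Ksv (decreasing -> static, increasing -> dynamic),
2. magnitude of Kq relative to the diffusion ceiling,
3. invariance of the fluorescence lifetime upon quencher addition.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from ._regression import ols
from .errors import InsufficientDataError, InsufficientEvidenceError, InvalidInputError
from .preprocess import TitrationSeries

#: Diffusion-limited ceiling for collisional quenching, L mol^-1 s^-1.
DYNAMIC_QUENCHING_CEILING = 2.0e10

#: Default fluorophore lifetime without quencher, seconds (tryptophan in albumin).
DEFAULT_TAU0 = 1.0e-8

#: Relative lifetime change below which the lifetime is considered unchanged.
DEFAULT_LIFETIME_INVARIANCE_THRESHOLD = 0.05


class MechanismLabel(str, enum.Enum):
    STATIC = "static"
    DYNAMIC = "dynamic"
    COMBINED_OR_AMBIGUOUS = "combined_or_ambiguous"


class Vote(str, enum.Enum):
    STATIC = "static"
    DYNAMIC = "dynamic"
    INCONCLUSIVE = "inconclusive"
    NOT_EVALUATED = "not_evaluated"


@dataclass(frozen=True)
class RuleOutcome:
    rule: str
    vote: Vote
    detail: str


@dataclass(frozen=True)
class QuenchingFit:
    """Per-temperature Stern–Volmer fit: Ksv (slope), intercept, Kq = Ksv/tau0."""

    temperature: float
    Ksv: float
    intercept: float
    tau0: float
    Kq: float
    r_squared: float
    n_points: int
    warnings: tuple = ()


@dataclass(frozen=True)
class MechanismVerdict:
    label: MechanismLabel
    evidence: tuple  # of RuleOutcome


def compute_kq(Ksv: float, tau0: float) -> float:
    """Bimolecular quenching rate coefficient Kq = Ksv / tau0 (L mol^-1 s^-1)."""
    if tau0 <= 0:
        raise InvalidInputError("tau0 must be positive")
    return Ksv / tau0


def fit_stern_volmer(series: TitrationSeries, tau0: float = DEFAULT_TAU0) -> QuenchingFit:
    """Least-squares Stern–Volmer fit of F0/F versus [Q] for one temperature."""
    if tau0 <= 0:
        raise InvalidInputError("tau0 must be positive")
    q = series.concentrations
    f = series.intensities
    if q.size < 3:
        raise InsufficientDataError("Stern–Volmer fit needs at least 3 titration points")
    if (f <= 0).any():
        raise InvalidInputError("all fluorescence intensities must be positive")
    ratio = series.f0 / f
    slope, intercept, r2 = ols(q, ratio)
    notes = []
    if abs(intercept - 1.0) > 0.1:
        notes.append(
            "Stern–Volmer intercept %.4f deviates from 1 by more than 0.1" % intercept
        )
    if slope < 0:
        notes.append("negative Stern–Volmer slope: intensities increase with quencher")
    return QuenchingFit(
        temperature=float(series.temperature),
        Ksv=slope,
        intercept=intercept,
        tau0=float(tau0),
        Kq=compute_kq(slope, tau0),
        r_squared=r2,
        n_points=int(q.size),
        warnings=tuple(notes),
    )


def _trend_rule(fits: Sequence[QuenchingFit]) -> RuleOutcome:
    temps = [f.temperature for f in fits]
    ksv = [f.Ksv for f in fits]
    detail = "Ksv by T: " + ", ".join("%g K -> %.4g" % (t, k) for t, k in zip(temps, ksv))
    if len(set(temps)) < 2:
        return RuleOutcome("ksv_temperature_trend", Vote.NOT_EVALUATED, "single temperature")
    if all(b < a for a, b in zip(ksv, ksv[1:])):
        return RuleOutcome(
            "ksv_temperature_trend", Vote.STATIC, detail + " (strictly decreasing)"
        )
    if all(b > a for a, b in zip(ksv, ksv[1:])):
        return RuleOutcome(
            "ksv_temperature_trend", Vote.DYNAMIC, detail + " (strictly increasing)"
        )
    return RuleOutcome("ksv_temperature_trend", Vote.INCONCLUSIVE, detail + " (non-monotone)")


def _kq_rule(fits: Sequence[QuenchingFit], ceiling: float) -> RuleOutcome:
    kqs = [f.Kq for f in fits]
    detail = "Kq values %s vs ceiling %.2g" % (["%.3g" % k for k in kqs], ceiling)
    if all(k > ceiling for k in kqs):
        return RuleOutcome("kq_vs_diffusion_ceiling", Vote.STATIC, detail + " (all above)")
    if all(k <= ceiling for k in kqs):
        return RuleOutcome("kq_vs_diffusion_ceiling", Vote.DYNAMIC, detail + " (all at/below)")
    return RuleOutcome("kq_vs_diffusion_ceiling", Vote.INCONCLUSIVE, detail + " (mixed)")


def _lifetime_rule(change: Optional[float], threshold: float) -> RuleOutcome:
    if change is None:
        return RuleOutcome("lifetime_invariance", Vote.NOT_EVALUATED, "no lifetime data")
    if change < 0:
        raise InvalidInputError("lifetime change fraction must be >= 0")
    detail = "relative lifetime change %.3g vs threshold %.3g" % (change, threshold)
    if change < threshold:
        return RuleOutcome("lifetime_invariance", Vote.STATIC, detail + " (invariant)")
    return RuleOutcome("lifetime_invariance", Vote.DYNAMIC, detail + " (lifetime responds)")


def classify_mechanism(
    fits: Sequence[QuenchingFit],
    lifetime_change_fraction: Optional[float] = None,
    *,
    kq_ceiling: float = DYNAMIC_QUENCHING_CEILING,
    lifetime_threshold: float = DEFAULT_LIFETIME_INVARIANCE_THRESHOLD,
) -> MechanismVerdict:
    """Vote-based static/dynamic classification from independent evidence.

    The verdict is ``static`` or ``dynamic`` only when every evaluated rule
    agrees; any disagreement or inconclusive rule yields
    ``combined_or_ambiguous`` with the full evidence trail attached.
    """
    if not fits:
        raise InvalidInputError("no quenching fits given")
    fits = sorted(fits, key=lambda f: f.temperature)
    n_temps = len({f.temperature for f in fits})
    if n_temps < 2 and lifetime_change_fraction is None:
        raise InsufficientEvidenceError(
            "a single temperature with no lifetime data cannot distinguish mechanisms"
        )
    outcomes = (
        _trend_rule(fits),
        _kq_rule(fits, kq_ceiling),
        _lifetime_rule(lifetime_change_fraction, lifetime_threshold),
    )
    cast = [o.vote for o in outcomes if o.vote is not Vote.NOT_EVALUATED]
    if all(v is Vote.STATIC for v in cast):
        label = MechanismLabel.STATIC
    elif all(v is Vote.DYNAMIC for v in cast):
        label = MechanismLabel.DYNAMIC
    else:
        label = MechanismLabel.COMBINED_OR_AMBIGUOUS
    return MechanismVerdict(label=label, evidence=outcomes)
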