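import itertools

import numpy as np
import pytest
from conftest import STUDY_TABLE, ols_oracle

from albind.errors import (
    InsufficientDataError,
    InsufficientEvidenceError,
    InvalidInputError,
)
from albind.preprocess import TitrationPoint, TitrationSeries
from albind.quenching import (
    DYNAMIC_QUENCHING_CEILING,
    MechanismLabel,
    QuenchingFit,
    Vote,
    classify_mechanism,
    compute_kq,
    fit_stern_volmer,
)


def series_from_ratio(concs, ratios, temperature=298.0, f0=1000.0):
    """Titration whose F0/F equals the given ratios exactly."""
    pts = tuple(
        TitrationPoint(quencher_conc=c, raw_intensity=f0 / r)
        for c, r in zip(concs, ratios)
    )
    return TitrationSeries(temperature=temperature, points=pts)


class TestSternVolmer:
    def test_recovers_study_ksv(self):
        ksv = STUDY_TABLE[298.0][0]
        q = np.linspace(0.0, 9e-6, 7)
        series = series_from_ratio(q, 1.0 + ksv * q)
        fit = fit_stern_volmer(series)
        assert fit.Ksv == pytest.approx(ksv, rel=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_intensity_gives_zero_slope(self):
        q = np.linspace(0.0, 9e-6, 5)
        fit = fit_stern_volmer(series_from_ratio(q, np.ones_like(q)))
        assert fit.Ksv == pytest.approx(0.0, abs=1e-6)  # L/mol, vs ~1e4 when quenched
        assert fit.intercept == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            q = np.r_[0.0, np.sort(rng.uniform(1e-7, 1e-5, 3))]
            ratios = 1.0 + rng.uniform(1e3, 1e5) * q + rng.normal(0, 0.02, 4)
            ratios = np.maximum(ratios, 0.1)
            series = series_from_ratio(q, ratios)
            fit = fit_stern_volmer(series)
            slope, intercept = ols_oracle(q, series.f0 / series.intensities)
            assert fit.Ksv == pytest.approx(slope, rel=1e-10)
            assert fit.intercept == pytest.approx(intercept, rel=1e-10)

    def test_too_few_points(self):
        q = np.array([0.0, 1e-6])
        with pytest.raises(InsufficientDataError):
            fit_stern_volmer(series_from_ratio(q, [1.0, 1.1]))

    def test_zero_intensity_rejected(self):
        pts = (TitrationPoint(0.0, 1000.0), TitrationPoint(1e-6, 0.0),
               TitrationPoint(2e-6, 10.0))
        with pytest.raises(InvalidInputError):
            fit_stern_volmer(TitrationSeries(temperature=298.0, points=pts))

    def test_intercept_drift_recorded(self):
        # a jump between the [Q]=0 point and the rest pushes the intercept off 1
        q = np.linspace(0.0, 9e-6, 5)
        fit = fit_stern_volmer(series_from_ratio(q, np.r_[1.0, 1.5 + 1e4 * q[1:]]))
        assert any("intercept" in w for w in fit.warnings)


class TestKq:
    @pytest.mark.parametrize("ksv, expected", [
        (7.85e4, 7.85e12), (7.31e4, 7.31e12), (6.18e4, 6.18e12), (0.0, 0.0),
    ])
    def test_study_values(self, ksv, expected):
        assert compute_kq(ksv, 1.0e-8) == pytest.approx(expected, rel=1e-12)

    def test_inverse_scaling_in_tau0(self):
        for c in (0.5, 2.0, 10.0):
            assert compute_kq(5e4, c * 1e-8) == pytest.approx(
                compute_kq(5e4, 1e-8) / c, rel=1e-12
            )

    def test_nonpositive_tau0_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_kq(1e4, 0.0)


def make_fits(ksv_values, kq_above):
    """QuenchingFits at 298/304/310 K with Kq placed above/below the ceiling.

    kq_above may be a single bool or one bool per temperature; tau0 is chosen
    per fit so that Kq lands on the requested side while Ksv follows the trend.
    """
    temps = (298.0, 304.0, 310.0)
    if isinstance(kq_above, bool):
        kq_above = (kq_above,) * len(temps)
    fits = []
    for t, ksv, above in zip(temps, ksv_values, kq_above):
        kq = 5.0 * DYNAMIC_QUENCHING_CEILING if above else 0.05 * DYNAMIC_QUENCHING_CEILING
        tau0 = ksv / kq
        fits.append(QuenchingFit(temperature=t, Ksv=ksv, intercept=1.0, tau0=tau0,
                                 Kq=kq, r_squared=1.0, n_points=7))
    return fits


TRENDS = {
    "decreasing": (7.85e4, 7.31e4, 6.18e4),
    "increasing": (6.18e4, 7.31e4, 7.85e4),
    "mixed": (7.85e4, 6.18e4, 7.31e4),
}


class TestMechanism:
    def test_study_evidence_pattern_is_static(self):
        fits = make_fits(TRENDS["decreasing"], kq_above=True)
        verdict = classify_mechanism(fits, lifetime_change_fraction=0.014)
        assert verdict.label is MechanismLabel.STATIC

    def test_all_dynamic_votes(self):
        fits = make_fits(TRENDS["increasing"], kq_above=False)
        verdict = classify_mechanism(fits, lifetime_change_fraction=0.20)
        assert verdict.label is MechanismLabel.DYNAMIC

    def test_conflicting_votes_are_ambiguous(self):
        fits = make_fits(TRENDS["decreasing"], kq_above=False)
        verdict = classify_mechanism(fits)
        assert verdict.label is MechanismLabel.COMBINED_OR_AMBIGUOUS

    def test_permutation_invariance(self):
        fits = make_fits(TRENDS["decreasing"], kq_above=True)
        for perm in itertools.permutations(fits):
            assert classify_mechanism(list(perm)).label is MechanismLabel.STATIC

    def test_single_temperature_without_lifetime_raises(self):
        fits = make_fits(TRENDS["decreasing"], kq_above=True)[:1]
        with pytest.raises(InsufficientEvidenceError):
            classify_mechanism(fits)

    @pytest.mark.parametrize("trend", list(TRENDS))
    @pytest.mark.parametrize("kq_pattern", ["above", "below", "mixed"])
    @pytest.mark.parametrize("lifetime", [None, 0.01, 0.20])
    def test_exhaustive_rule_table(self, trend, kq_pattern, lifetime):
        """Every combination of rule outcomes maps to the vote-table verdict."""
        kq_above = {"above": True, "below": False, "mixed": (True, False, True)}[kq_pattern]
        fits = make_fits(TRENDS[trend], kq_above)
        verdict = classify_mechanism(fits, lifetime_change_fraction=lifetime)

        votes = []
        votes.append({"decreasing": Vote.STATIC, "increasing": Vote.DYNAMIC,
                      "mixed": Vote.INCONCLUSIVE}[trend])
        votes.append({"above": Vote.STATIC, "below": Vote.DYNAMIC,
                      "mixed": Vote.INCONCLUSIVE}[kq_pattern])
        if lifetime is not None:
            votes.append(Vote.STATIC if lifetime < 0.05 else Vote.DYNAMIC)
        if all(v is Vote.STATIC for v in votes):
            expected = MechanismLabel.STATIC
        elif all(v is Vote.DYNAMIC for v in votes):
            expected = MechanismLabel.DYNAMIC
        else:
            expected = MechanismLabel.COMBINED_OR_AMBIGUOUS
        assert verdict.label is expected
        # a static verdict must never coexist with a dynamic vote
        if verdict.label is MechanismLabel.STATIC:
            assert all(o.vote is not Vote.DYNAMIC for o in verdict.evidence)
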