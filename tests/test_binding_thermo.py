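import math

import numpy as np
import pytest
from conftest import STUDY_DELTA_H, STUDY_DELTA_S, STUDY_TABLE, ols_oracle
from hypothesis import given, settings
from hypothesis import strategies as st

from albind.binding_thermo import (
    GAS_CONSTANT,
    BindingFit,
    ForceLabel,
    analyze_thermodynamics,
    classify_forces,
    fit_double_log,
    fit_vant_hoff,
    gibbs,
)
from albind.errors import InsufficientDataError, InvalidInputError, UnclassifiableError
from albind.preprocess import TitrationPoint, TitrationSeries


def isotherm_series(ka, n, concs=None, f0=1000.0, temperature=298.0):
    """Noiseless titration obeying (F0 - F)/F = Ka * [Q]^n exactly."""
    if concs is None:
        concs = np.linspace(0.0, 9e-6, 7)
    f = f0 / (1.0 + ka * np.where(concs > 0, concs, 0.0) ** n)
    f[concs == 0] = f0
    pts = tuple(TitrationPoint(quencher_conc=float(c), raw_intensity=float(v))
                for c, v in zip(concs, f))
    return TitrationSeries(temperature=temperature, points=pts)


class TestDoubleLog:
    def test_recovers_study_parameters(self):
        ka, n = STUDY_TABLE[298.0][2], STUDY_TABLE[298.0][1]
        fit = fit_double_log(isotherm_series(ka, n))
        assert fit.Ka == pytest.approx(ka, rel=1e-9)
        assert fit.n_sites == pytest.approx(n, rel=1e-9)

    def test_reduces_to_stern_volmer_at_unit_n(self):
        fit = fit_double_log(isotherm_series(7.85e4, 1.0))
        assert fit.n_sites == pytest.approx(1.0, rel=1e-10)
        assert fit.Ka == pytest.approx(7.85e4, rel=1e-10)

    @pytest.mark.parametrize("n", [0.5, 0.8, 1.14, 1.6, 2.0])
    def test_recovery_across_stoichiometries(self, n):
        # Ka scaled so the mid-titration occupancy is comparable at every n;
        # otherwise F0 - F underflows toward machine precision at large n
        ka = 0.5 * (4.5e-6) ** (-n)
        fit = fit_double_log(isotherm_series(ka, n))
        assert fit.Ka == pytest.approx(ka, rel=1e-9)
        assert fit.n_sites == pytest.approx(n, rel=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            q = np.r_[0.0, np.sort(rng.uniform(5e-7, 1e-5, 5))]
            series = isotherm_series(rng.uniform(1e4, 1e6), rng.uniform(0.6, 1.6), q)
            noisy_pts = [series.points[0]]
            for p in series.points[1:]:
                noisy_pts.append(TitrationPoint(
                    quencher_conc=p.quencher_conc,
                    raw_intensity=p.raw_intensity * rng.uniform(0.97, 0.995),
                ))
            series = TitrationSeries(temperature=298.0, points=tuple(noisy_pts))
            fit = fit_double_log(series)
            f0 = series.f0
            mask = series.concentrations > 0
            x = np.log10(series.concentrations[mask])
            y = np.log10((f0 - series.intensities[mask]) / series.intensities[mask])
            slope, intercept = ols_oracle(x, y)
            assert fit.n_sites == pytest.approx(slope, rel=1e-10)
            assert fit.Ka == pytest.approx(10 ** intercept, rel=1e-10)

    def test_no_quenching_rejected(self):
        pts = (TitrationPoint(0.0, 1000.0), TitrationPoint(1e-6, 1000.0),
               TitrationPoint(2e-6, 900.0), TitrationPoint(3e-6, 800.0))
        with pytest.raises(InvalidInputError):
            fit_double_log(TitrationSeries(temperature=298.0, points=pts))

    def test_too_few_usable_points(self):
        with pytest.raises(InsufficientDataError):
            fit_double_log(isotherm_series(1e5, 1.0, np.array([0.0, 1e-6, 2e-6])))


class TestVantHoff:
    def test_study_ka_triplet(self):
        """The printed Ka values reproduce the printed (dH, dS) within 1%."""
        fits = [BindingFit(temperature=t, Ka=row[2], n_sites=row[1], r_squared=1.0)
                for t, row in STUDY_TABLE.items()]
        vh = fit_vant_hoff(fits)
        assert vh.delta_H == pytest.approx(STUDY_DELTA_H, rel=0.01)
        assert vh.delta_S == pytest.approx(STUDY_DELTA_S, rel=0.01)

    def test_equal_ka_means_zero_enthalpy(self):
        fits = [BindingFit(temperature=t, Ka=2e5, n_sites=1.0, r_squared=1.0)
                for t in (298.0, 310.0)]
        vh = fit_vant_hoff(fits)
        assert vh.delta_H == pytest.approx(0.0, abs=1e-6)

    def test_two_point_closed_form(self):
        # ln Ka = 10 - 2000/T  =>  dH = 2000 R, dS = 10 R
        fits = [BindingFit(temperature=t, Ka=math.exp(10 - 2000 / t),
                           n_sites=1.0, r_squared=1.0) for t in (298.0, 310.0)]
        vh = fit_vant_hoff(fits)
        assert vh.delta_H == pytest.approx(2000 * GAS_CONSTANT, rel=1e-10)
        assert vh.delta_S == pytest.approx(10 * GAS_CONSTANT, rel=1e-10)

    @given(
        delta_H=st.floats(-2e5, 2e5),
        delta_S=st.floats(-500.0, 500.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_round_trip_property(self, delta_H, delta_S):
        """Exact Van 't Hoff data is refit to (dH, dS) within 1e-9 relative."""
        fits = [
            BindingFit(
                temperature=t,
                Ka=math.exp(-delta_H / (GAS_CONSTANT * t) + delta_S / GAS_CONSTANT),
                n_sites=1.0,
                r_squared=1.0,
            )
            for t in (288.0, 298.0, 308.0, 318.0)
        ]
        vh = fit_vant_hoff(fits)
        assert vh.delta_H == pytest.approx(delta_H, rel=1e-9, abs=1e-4)
        assert vh.delta_S == pytest.approx(delta_S, rel=1e-9, abs=1e-7)

    def test_duplicate_temperature_conflict(self):
        fits = [BindingFit(temperature=298.0, Ka=1e5, n_sites=1.0, r_squared=1.0),
                BindingFit(temperature=298.0, Ka=2e5, n_sites=1.0, r_squared=1.0)]
        with pytest.raises(InvalidInputError):
            fit_vant_hoff(fits)

    def test_single_temperature_insufficient(self):
        with pytest.raises(InsufficientDataError):
            fit_vant_hoff([BindingFit(temperature=298.0, Ka=1e5, n_sites=1.0,
                                      r_squared=1.0)])


class TestGibbs:
    @pytest.mark.parametrize("t, expected", [
        (298.0, -31918.9), (304.0, -30170.5), (310.0, -28422.2),
    ])
    def test_study_values(self, t, expected):
        assert gibbs(STUDY_DELTA_H, STUDY_DELTA_S, t) == pytest.approx(expected, rel=1e-4)

    def test_zero_case(self):
        assert gibbs(0.0, 0.0, 310.0) == 0.0

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(InvalidInputError):
            gibbs(-1e5, -300.0, 0.0)


class TestForces:
    @pytest.mark.parametrize("dH, dS, expected", [
        (-118750.0, -291.38, ForceLabel.VDW_HBOND),
        (5000.0, 100.0, ForceLabel.HYDROPHOBIC),
        (-2000.0, 50.0, ForceLabel.ELECTROSTATIC),
        (0.0, 50.0, ForceLabel.ELECTROSTATIC),
    ])
    def test_sign_taxonomy(self, dH, dS, expected):
        assert classify_forces(dH, dS) is expected

    def test_outside_taxonomy_raises(self):
        with pytest.raises(UnclassifiableError):
            classify_forces(5000.0, -50.0)


class TestThermoResult:
    def test_gibbs_identity_is_exact(self):
        fits = [BindingFit(temperature=t, Ka=row[2], n_sites=row[1], r_squared=1.0)
                for t, row in STUDY_TABLE.items()]
        res = analyze_thermodynamics(fits)
        for t, dg in res.delta_G_by_T.items():
            assert dg == res.delta_H - t * res.delta_S  # bit-for-bit

    def test_rt_lnka_cross_check_close_to_gibbs(self):
        fits = [BindingFit(temperature=t, Ka=row[2], n_sites=row[1], r_squared=1.0)
                for t, row in STUDY_TABLE.items()]
        res = analyze_thermodynamics(fits)
        for t in res.delta_G_by_T:
            assert res.delta_G_rt_lnka_by_T[t] == pytest.approx(
                res.delta_G_by_T[t], rel=0.01
            )

    def test_exothermic_binding_weakens_with_temperature(self, truth):
        """Fitted dH < 0 goes with Ka monotonically decreasing in T."""
        temps = (298.0, 304.0, 310.0)
        fits = [BindingFit(temperature=t, Ka=truth.ka_at(t), n_sites=truth.n_sites,
                           r_squared=1.0) for t in temps]
        res = analyze_thermodynamics(fits)
        assert res.delta_H < 0
        kas = [truth.ka_at(t) for t in temps]
        assert all(b < a for a, b in zip(kas, kas[1:]))
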