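"""Structural model behaviour: closed form vs ODE, superposition, limits."""

import numpy as np
import pytest

import mmdose as m
from mmdose.pk import InvalidParameterError

from conftest import ode_oracle


class TestEffectiveDisposition:
    def test_covariate_terms_vanish(self, median_cov):
        p = m.CovariateLinearParams(3.0, 0.0, 10.0, 0.0, 1.0, 1.0)
        assert m.effective_disposition(p, median_cov) == (3.0, 10.0)

    def test_population_means_at_median_covariates(self, median_cov):
        p = m.CovariateLinearParams(3.83, 0.11, 4.54, 0.12, 6.74, 9.14)
        cl, vc = m.effective_disposition(p, median_cov)
        assert cl == pytest.approx(12.74)
        assert vc == pytest.approx(12.82)

    def test_degenerate_raises(self, median_cov):
        p = m.CovariateLinearParams(0.0, 0.0, 1.0, 0.0, 1.0, 1.0)
        with pytest.raises(InvalidParameterError):
            m.effective_disposition(p, median_cov)

    def test_invalid_covariates_rejected(self):
        with pytest.raises(InvalidParameterError):
            m.PatientCovariates("x", crcl=-1.0, weight=70.0)


class TestSimulateProfile:
    def test_empty_regimen_all_zero(self, linear_params):
        prof = m.simulate_profile(linear_params, m.Regimen(()), [0.0, 1.0, 5.0])
        assert np.all(prof.concentrations == 0.0)

    def test_continuous_infusion_steady_state(self, linear_params):
        # C -> R/cl after many half-lives of constant-rate input
        rate = 500.0  # mg/h
        reg = m.Regimen((m.DoseEvent(0.0, 200.0, rate * 200.0),))
        prof = m.simulate_profile(linear_params, reg, [150.0])
        assert prof.concentrations[0] == pytest.approx(rate / linear_params.cl, rel=1e-6)

    @pytest.mark.parametrize("params", [
        m.LinearParams(10.89, 5.97, 0.85, 1.65),
        m.LinearParams(3.0, 25.0, 6.74, 9.14),
        m.LinearParams(25.0, 4.0, 0.1, 0.1),
    ])
    def test_closed_form_matches_rk45(self, params, q8h_regimen):
        times = np.linspace(0.1, 24.0, 60)
        closed = m.simulate_profile(params, q8h_regimen, times).concentrations
        oracle = ode_oracle(params, q8h_regimen, times)
        assert np.max(np.abs(closed - oracle)) < 1e-6

    def test_covariate_model_reduces_to_effective_linear(self, median_params,
                                                         median_cov, q8h_regimen):
        times = np.linspace(0.5, 24.0, 30)
        cl, vc = m.effective_disposition(median_params, median_cov)
        eff = m.LinearParams(cl, vc, median_params.kcp, median_params.kpc)
        a = m.simulate_profile(median_params, q8h_regimen, times, cov=median_cov)
        b = m.simulate_profile(eff, q8h_regimen, times)
        np.testing.assert_allclose(a.concentrations, b.concentrations, atol=1e-12)

    def test_covariate_model_requires_covariates(self, median_params, q8h_regimen):
        with pytest.raises(InvalidParameterError):
            m.simulate_profile(median_params, q8h_regimen, [1.0])

    def test_mm_limit_matches_linear(self, linear_params, q8h_regimen):
        # km >> C collapses saturable elimination to clearance vmax/km
        km = 1e6
        mmp = m.MMParams(vmax=km * linear_params.cl, km=km,
                         vc=linear_params.vc, kcp=linear_params.kcp,
                         kpc=linear_params.kpc)
        times = np.linspace(0.25, 24.0, 40)
        a = m.simulate_profile(mmp, q8h_regimen, times).concentrations
        b = m.simulate_profile(linear_params, q8h_regimen, times).concentrations
        mask = b > 0.5
        assert np.max(np.abs(a[mask] - b[mask]) / b[mask]) < 0.005

    def test_parallel_adds_clearances_in_mm_limit(self, q8h_regimen):
        km = 1e6
        pp = m.ParallelParams(cl=5.0, vmax=km * 5.89, km=km, vc=5.97,
                              kcp=0.85, kpc=1.65)
        lin = m.LinearParams(10.89, 5.97, 0.85, 1.65)
        times = np.linspace(0.25, 10.0, 20)
        a = m.simulate_profile(pp, q8h_regimen, times).concentrations
        b = m.simulate_profile(lin, q8h_regimen, times).concentrations
        mask = b > 0.5
        assert np.max(np.abs(a[mask] - b[mask]) / b[mask]) < 0.005

    def test_superposition(self, linear_params):
        times = np.linspace(0.1, 20.0, 40)
        a = m.Regimen((m.DoseEvent(0.0, 0.5, 4000.0),))
        b = m.Regimen((m.DoseEvent(6.0, 4.0, 3000.0),))
        ca = m.simulate_profile(linear_params, a, times).concentrations
        cb = m.simulate_profile(linear_params, b, times).concentrations
        cab = m.simulate_profile(linear_params, a + b, times).concentrations
        assert np.max(np.abs(cab - (ca + cb))) < 1e-6

    def test_dose_linearity(self, linear_params, q8h_regimen):
        times = np.linspace(0.1, 24.0, 30)
        c1 = m.simulate_profile(linear_params, q8h_regimen, times).concentrations
        c3 = m.simulate_profile(linear_params, q8h_regimen.scaled(3.0), times).concentrations
        np.testing.assert_allclose(c3, 3.0 * c1, rtol=1e-12)

    def test_mass_balance_without_elimination(self):
        # cl -> 0: everything infused stays in the two compartments
        p = m.LinearParams(cl=1e-9, vc=10.0, kcp=1.0, kpc=2.0)
        reg = m.Regimen((m.DoseEvent(0.0, 2.0, 1000.0),))
        from mmdose.pk import _simulate_states
        states = _simulate_states("linear", p.cl, None, None, p.vc, p.kcp, p.kpc,
                                  reg, np.array([5.0]))
        assert states[0].sum() == pytest.approx(1000.0, rel=1e-6)

    def test_left_limit_at_infusion_start(self, linear_params):
        # a later infusion contributes nothing at its own start instant
        one = m.Regimen((m.DoseEvent(0.0, 0.5, 4000.0),))
        two = one + m.Regimen((m.DoseEvent(8.0, 0.5, 4000.0),))
        c_one = m.simulate_profile(linear_params, one, [8.0]).concentrations[0]
        c_two = m.simulate_profile(linear_params, two, [8.0]).concentrations[0]
        assert c_two == pytest.approx(c_one, abs=1e-12)

    def test_unsorted_times_rejected(self, linear_params, q8h_regimen):
        with pytest.raises(ValueError):
            m.simulate_profile(linear_params, q8h_regimen, [5.0, 1.0])


class TestSteadyStateTrough:
    def test_zero_dose(self, linear_params):
        assert m.steady_state_trough(linear_params, 0.0, 8.0, 0.5) == 0.0

    def test_closed_form_matches_repeated_simulation(self, linear_params):
        tr = m.steady_state_trough(linear_params, 4000.0, 8.0, 0.5)
        reg = m.repeated_doses(4000.0, 8.0, 0.5, n_doses=15)
        sim = m.simulate_profile(linear_params, reg, [15 * 8.0]).concentrations[0]
        assert tr == pytest.approx(sim, rel=1e-3)

    def test_dose_doubling_doubles_trough(self, linear_params):
        t1 = m.steady_state_trough(linear_params, 4000.0, 8.0, 0.5)
        t2 = m.steady_state_trough(linear_params, 8000.0, 8.0, 0.5)
        assert t2 == pytest.approx(2.0 * t1, rel=1e-12)

    def test_mm_iterative_agrees_with_near_linear(self, linear_params):
        km = 1e6
        mmp = m.MMParams(vmax=km * linear_params.cl, km=km, vc=linear_params.vc,
                         kcp=linear_params.kcp, kpc=linear_params.kpc)
        a = m.steady_state_trough(mmp, 4000.0, 8.0, 0.5)
        b = m.steady_state_trough(linear_params, 4000.0, 8.0, 0.5)
        assert a == pytest.approx(b, rel=0.01)

    def test_interval_must_exceed_duration(self, linear_params):
        with pytest.raises(ValueError):
            m.steady_state_trough(linear_params, 4000.0, 0.5, 0.5)
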