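"""Multiple-model dose selection and inverse dose estimation."""

import numpy as np
import pytest

import mmdose as m
from mmdose.optimize import FlatObjectiveError


@pytest.fixture
def empty_past(median_cov):
    return m.PatientPast(median_cov, m.Regimen(()), ())


@pytest.fixture
def single_point_post(median_params):
    return m.DiscreteDistribution(
        [m.SupportPoint(median_params, 1.0)], "linear_covariate")


def _template(durations, start=0.0, interval=8.0, bounds=(10.0, 1e7)):
    n = len(durations)
    return m.FutureTemplate(tuple(start + interval * k for k in range(n)),
                            tuple(durations), dose_bounds=bounds)


class TestExpectedWsse:
    def test_exact_attainment_gives_zero(self, single_point_post, empty_past,
                                         error_model):
        tmpl = _template([0.5])
        tgt_time = 6.0
        rec = m.optimize_dose(single_point_post, empty_past, tmpl,
                              m.TargetSpec(((tgt_time, 10.0, None),)),
                              error=error_model)
        wsse = m.expected_wsse(single_point_post, empty_past, tmpl, rec.dose,
                               m.TargetSpec(((tgt_time, 10.0, None),)),
                               error=error_model)
        assert wsse == pytest.approx(0.0, abs=1e-12)

    def test_zero_weights_give_zero(self, single_point_post, empty_past):
        tmpl = _template([0.5])
        tgt = m.TargetSpec(((6.0, 10.0, 0.0),))
        assert m.expected_wsse(single_point_post, empty_past, tmpl, 5000.0,
                               tgt) == 0.0

    def test_matches_brute_force_double_loop(self, three_point_prior,
                                             median_cov, error_model):
        past = m.PatientPast(median_cov,
                             m.Regimen((m.DoseEvent(0.0, 0.5, 2000.0),)),
                             ((1.0, 40.0),))
        tmpl = _template([0.5], start=8.0)
        tgt = m.TargetSpec(((10.0, 30.0, 2.0), (14.0, 8.0, 1.0)))
        dose = 3500.0
        got = m.expected_wsse(three_point_prior, past, tmpl, dose, tgt,
                              error=error_model)
        brute = 0.0
        full = past.regimen + tmpl.regimen(dose)
        for pt in three_point_prior.points:
            pred = m.simulate_profile(pt.params, full, tgt.times).concentrations
            for lam, (t, goal, _) in zip((2.0, 1.0), tgt.targets):
                c = pred[list(tgt.times).index(t)]
                brute += pt.probability * lam * (c - goal) ** 2
        assert got == pytest.approx(brute, rel=1e-12)


class TestOptimizeDose:
    def test_single_point_trough_exact(self, single_point_post, empty_past,
                                       median_cov, median_params, error_model):
        tmpl = _template([0.5] * 4)
        tgt = m.TargetSpec(((4 * 8.0, 13.6, None),))
        rec = m.optimize_dose(single_point_post, empty_past, tmpl, tgt,
                              error=error_model)
        assert rec.achieved_targets[0] == pytest.approx(13.6, rel=1e-9)

    def test_closed_form_matches_grid_sweep(self, three_point_prior,
                                            median_cov, error_model):
        past = m.PatientPast(median_cov, m.Regimen(()), ())
        tmpl = _template([0.5] * 2, bounds=(100.0, 20000.0))
        tgt = m.TargetSpec(((8.0, 25.0, None), (16.0, 25.0, None)))
        rec = m.optimize_dose(three_point_prior, past, tmpl, tgt,
                              error=error_model)
        grid = np.arange(100.0, 20000.0, 10.0)
        vals = [m.expected_wsse(three_point_prior, past, tmpl, d, tgt,
                                error=error_model) for d in grid]
        best = grid[int(np.argmin(vals))]
        assert abs(rec.dose - best) <= 10.0
        assert rec.expected_wsse <= min(vals) + 1e-9

    def test_optimizer_dominates_dose_sweep(self, three_point_prior, median_cov,
                                            error_model):
        past = m.PatientPast(median_cov,
                             m.Regimen((m.DoseEvent(0.0, 0.5, 4000.0),)),
                             ((1.0, 60.0),))
        post = m.posterior_update(three_point_prior, past, error_model)
        tmpl = _template([0.5], start=8.0, bounds=(100.0, 20000.0))
        tgt = m.TargetSpec(((14.0, 12.0, None),))
        rec = m.optimize_dose(post, past, tmpl, tgt, error=error_model)
        sweep = np.linspace(100.0, 20000.0, 200)
        vals = [m.expected_wsse(post, past, tmpl, d, tgt, error=error_model)
                for d in sweep]
        assert rec.expected_wsse <= min(vals) + 1e-9

    def test_mm_kind_brent_matches_grid(self, median_cov, error_model):
        pts = [m.SupportPoint(m.MMParams(2000.0, 80.0, 12.0, 1.0, 1.0), 0.6),
               m.SupportPoint(m.MMParams(1500.0, 60.0, 15.0, 1.0, 1.0), 0.4)]
        post = m.DiscreteDistribution(pts, "michaelis_menten")
        past = m.PatientPast(median_cov, m.Regimen(()), ())
        tmpl = _template([0.5], bounds=(100.0, 20000.0))
        tgt = m.TargetSpec(((6.0, 20.0, None),))
        rec = m.optimize_dose(post, past, tmpl, tgt, error=error_model)
        grid = np.arange(100.0, 20000.0, 100.0)
        vals = [m.expected_wsse(post, past, tmpl, d, tgt, error=error_model)
                for d in grid]
        best = grid[int(np.argmin(vals))]
        assert abs(rec.dose - best) <= 100.0 + tmpl.dose_grid_step

    def test_raising_targets_never_lowers_dose(self, three_point_prior,
                                               median_cov, error_model):
        past = m.PatientPast(median_cov, m.Regimen(()), ())
        tmpl = _template([0.5] * 2)
        lo = m.optimize_dose(three_point_prior, past, tmpl,
                             m.TargetSpec(((8.0, 10.0, 1.0), (16.0, 10.0, 1.0))),
                             error=error_model)
        hi = m.optimize_dose(three_point_prior, past, tmpl,
                             m.TargetSpec(((8.0, 20.0, 1.0), (16.0, 20.0, 1.0))),
                             error=error_model)
        assert hi.dose >= lo.dose

    def test_flat_objective_raises(self, single_point_post, empty_past,
                                   error_model):
        # target before any future dose is administered: no dose signal
        tmpl = m.FutureTemplate((10.0,), (0.5,), dose_bounds=(10.0, 1e6))
        tgt = m.TargetSpec(((5.0, 10.0, None),))
        with pytest.raises(FlatObjectiveError):
            m.optimize_dose(single_point_post, empty_past, tmpl, tgt,
                            error=error_model)

    def test_out_of_bounds_optimum_clipped_and_flagged(self, single_point_post,
                                                       empty_past, error_model):
        tmpl = _template([0.5], bounds=(100.0, 500.0))
        tgt = m.TargetSpec(((6.0, 200.0, None),))
        rec = m.optimize_dose(single_point_post, empty_past, tmpl, tgt,
                              error=error_model)
        assert rec.clipped and rec.dose == 500.0


class TestEstimateDeliveredDose:
    @pytest.mark.parametrize("params", [
        m.LinearParams(10.89, 5.97, 0.85, 1.65),
        m.MMParams(800.0, 40.0, 10.0, 0.85, 1.65),
    ])
    def test_inverse_consistency(self, params, median_cov, error_model):
        # targets simulated at a known dose with the same single-point
        # posterior must return that dose
        kind = params.model_kind
        post = m.DiscreteDistribution([m.SupportPoint(params, 1.0)], kind)
        past_reg = m.repeated_doses(4000.0, 8.0, 0.5, n_doses=3)
        past = m.PatientPast(median_cov, past_reg, ((0.5, 100.0), (6.0, 2.0)))
        true_dose = 4000.0
        tmpl = m.FutureTemplate((24.0,), (0.5,), dose_bounds=(100.0, 20000.0))
        times = [24.5, 25.0, 26.0, 28.0]
        full = past_reg + tmpl.regimen(true_dose)
        sim = m.simulate_profile(params, full, times).concentrations
        tgt = m.TargetSpec(tuple((t, float(c), None) for t, c in zip(times, sim)))
        rec, pct = m.estimate_delivered_dose(post, past, tmpl, tgt,
                                             reference_dose=true_dose,
                                             error=error_model)
        tol = 1e-6 if kind == "linear" else tmpl.dose_grid_step / true_dose
        assert rec.dose == pytest.approx(true_dose, rel=max(tol, 1e-6))

    def test_percent_deviation_arithmetic(self, single_point_post, empty_past,
                                          error_model, monkeypatch):
        tmpl = _template([0.5])
        tgt = m.TargetSpec(((6.0, 10.0, None),))
        rec, pct = m.estimate_delivered_dose(
            single_point_post, empty_past, tmpl, tgt, reference_dose=4000.0,
            error=error_model)
        expected = 100.0 * (rec.dose - 4000.0) / 4000.0
        assert pct == pytest.approx(expected)
        # the printed convention: 4020 vs 4000 -> +0.5%
        assert 100.0 * (4020.0 - 4000.0) / 4000.0 == pytest.approx(0.5)
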