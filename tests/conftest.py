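import numpy as np
import pytest

import mmdose as m


@pytest.fixture
def error_model():
    return m.AssayErrorModel()


@pytest.fixture
def median_cov():
    """Covariates at the pooled cohort medians."""
    return m.PatientCovariates("median", crcl=81.0, weight=69.0)


@pytest.fixture
def median_params():
    """Population-median covariate-linear parameter vector."""
    return m.CovariateLinearParams(cl_i=2.79, cl_s=0.10, v_i=1.83, v_s=0.06,
                                   kcp=0.85, kpc=1.65)


@pytest.fixture
def linear_params():
    """Effective disposition of the median patient, as a plain linear model."""
    return m.LinearParams(cl=10.89, vc=5.97, kcp=0.85, kpc=1.65)


@pytest.fixture
def q8h_regimen():
    """Three 4 g doses as 30-min infusions every 8 h."""
    return m.repeated_doses(4000.0, 8.0, 0.5, n_doses=3)


@pytest.fixture
def three_point_prior():
    pts = [
        m.SupportPoint(m.LinearParams(5.0, 10.0, 1.0, 1.0), 0.3),
        m.SupportPoint(m.LinearParams(10.0, 15.0, 1.0, 1.0), 0.5),
        m.SupportPoint(m.LinearParams(15.0, 20.0, 1.0, 1.0), 0.2),
    ]
    return m.DiscreteDistribution(pts, "linear")


def ode_oracle(params, regimen, times, rtol=1e-9):
    """Segment-wise RK45 reference solution for a linear model."""
    from scipy.integrate import solve_ivp

    times = np.asarray(times, dtype=float)
    ke = params.cl / params.vc
    t_end = float(times.max())
    bps = regimen.rate_breakpoints()
    bps = np.unique(np.concatenate([bps[bps < t_end], [0.0, t_end]]))
    vals = np.zeros_like(times)
    x = np.zeros(2)
    for s, e in zip(bps[:-1], bps[1:]):
        rate = regimen.rate_at(s)
        mask = (times > s) & (times <= e)
        t_eval = np.unique(np.concatenate([times[mask] - s, [e - s]]))
        sol = solve_ivp(
            lambda t, y: [rate - (ke + params.kcp) * y[0] + params.kpc * y[1],
                          params.kcp * y[0] - params.kpc * y[1]],
            (0.0, e - s), x, method="RK45", rtol=rtol, atol=1e-12, t_eval=t_eval)
        idx = np.searchsorted(sol.t, times[mask] - s)
        vals[mask] = sol.y[0, idx] / params.vc
        x = sol.y[:, -1]
    return vals
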