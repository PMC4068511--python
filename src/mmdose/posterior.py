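"""Per-patient Bayesian posterior over the fixed population support points.

Given a patient's dosing history and measured concentrations, the
population distribution (the Bayesian prior) is reweighted by the
likelihood of those observations under each support point.  The support
locations never move — only their relative probabilities change — so the
posterior remains a discrete distribution over the same parameter
vectors and every downstream computation (prediction, dose selection)
is an expectation over it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assay import AssayErrorModel
from .pk import PatientCovariates, Regimen, simulate_profile
from .prior import DiscreteDistribution

_LOG_2PI = float(np.log(2.0 * np.pi))


class PosteriorUnderflowError(RuntimeError):
    """All support points are at likelihood underflow for these data."""


@dataclass(frozen=True)
class PatientPast:
    """Dosing history plus TDM observations for one patient."""

    covariates: PatientCovariates
    regimen: Regimen
    observations: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        times = [t for t, _ in self.observations]
        if any(t < 0 for t in times):
            raise ValueError("observation times must be >= 0")
        if sorted(times) != times:
            raise ValueError("observation times must be sorted")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.observations])

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for _, c in self.observations])


def _log_likelihoods(dist: DiscreteDistribution, past: PatientPast,
                     error: AssayErrorModel, use_observed_sd: bool) -> np.ndarray:
    obs = past.concentrations
    lls = np.empty(len(dist))
    for j, pt in enumerate(dist.points):
        pred = simulate_profile(pt.params, past.regimen, past.times,
                                cov=past.covariates).concentrations
        sd = np.asarray(error.sd_at(obs if use_observed_sd else pred))
        var = error.gamma * sd**2
        with np.errstate(over="ignore"):  # off-scale residuals -> -inf loglik
            lls[j] = float(np.sum(-0.5 * (_LOG_2PI + np.log(var))
                                  - (obs - pred) ** 2 / (2.0 * var)))
    return lls


def posterior_update(prior: DiscreteDistribution, past: PatientPast,
                     error: AssayErrorModel,
                     use_observed_sd: bool = False) -> DiscreteDistribution:
    """Reweight the prior by the likelihood of the patient's observations.

    The likelihood is a product of normal densities with mean equal to
    the model-predicted concentration and variance ``gamma * SD(pred)^2``
    (the assay polynomial evaluated at the predicted concentration, as in
    the fitting stage; ``use_observed_sd`` switches to the observed
    concentration for sensitivity checks).  Computed in log space; with
    no observations the posterior equals the prior.
    """
    if not past.observations:
        return prior
    log_lik = _log_likelihoods(prior, past, error, use_observed_sd)
    log_post = np.log(prior.probabilities()) + log_lik
    shift = log_post.max()
    if not np.isfinite(shift):
        raise PosteriorUnderflowError(
            "every support point underflows on these observations; check "
            "units (mg/L, h) and that observation times match the regimen"
        )
    post = np.exp(log_post - shift)
    return prior.reweighted(post)


def posterior_predict(post: DiscreteDistribution, past: PatientPast,
                      future_regimen: Regimen, times) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-weighted mean and median concentration profiles.

    The past and future regimens are concatenated (shared clock: hours
    from the first past dose) and simulated per support point; the
    weighted median is computed per time point.
    """
    times = np.asarray(times, dtype=float)
    full = past.regimen + future_regimen
    w = post.probabilities()
    profiles = np.empty((len(post), times.size))
    for j, pt in enumerate(post.points):
        profiles[j] = simulate_profile(pt.params, full, times,
                                       cov=past.covariates).concentrations
    mean = w @ profiles
    median = np.empty(times.size)
    for k in range(times.size):
        order = np.argsort(profiles[:, k])
        cum = np.cumsum(w[order])
        median[k] = profiles[order, k][np.searchsorted(cum, 0.5)]
    return mean, median


def posterior_summary(post: DiscreteDistribution):
    """Weighted mean / median / SD per parameter of the posterior."""
    return post.summarize()
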