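"""Nonparametric maximum-likelihood population PK estimation.

The population distribution of PK parameters is estimated as a discrete
mixing distribution: a grid of candidate support points is laid over the
parameter space and their probabilities are driven to the nonparametric
maximum-likelihood solution by the classical multiplicative EM update

    w_j  <-  (1/N) * sum_i  L_ij w_j / sum_k L_ik w_k

which is monotone in the marginal log likelihood and, because the NPML
problem is concave in the weights, converges to the same optimum as
interior-point solvers.  An adaptive-grid flavour is provided by
perturbing the surviving support points axis-wise (+/-20%) and re-solving
until the log likelihood stops improving.

The public surface follows the Model/Results convention: build an
``NPMLModel`` from subject data, call ``fit()``, inspect the returned
``NPMLResults`` (distribution, log likelihood, AIC, gamma, obs-pred
regressions, ``summary()``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, qmc

from .assay import AssayErrorModel
from .pk import (PatientCovariates, Regimen, param_names, params_from_vector,
                 simulate_profile)
from .prior import DiscreteDistribution

_LOG_2PI = float(np.log(2.0 * np.pi))
_TINY = np.finfo(float).tiny

# Nested model pairs (restricted, general) for likelihood-ratio testing.
_NESTED = {
    ("linear", "parallel"),
    ("michaelis_menten", "parallel"),
    ("linear", "linear_covariate"),
}


@dataclass(frozen=True)
class SubjectData:
    """One subject's dosing history, covariates and TDM observations."""

    covariates: PatientCovariates
    regimen: Regimen
    observations: tuple[tuple[float, float], ...]  # (time h, conc mg/L)

    def __post_init__(self) -> None:
        if not self.observations:
            raise ValueError("a subject needs at least one observation")
        times = [t for t, _ in self.observations]
        if sorted(times) != times:
            raise ValueError("observation times must be sorted")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.observations])

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for _, c in self.observations])


def _prediction_tensor(subjects: Sequence[SubjectData],
                       candidates: DiscreteDistribution) -> list[np.ndarray]:
    """Model-predicted concentrations: per subject, (n_points, n_obs)."""
    preds = []
    for subj in subjects:
        rows = np.empty((len(candidates), len(subj.observations)))
        for j, pt in enumerate(candidates.points):
            rows[j] = simulate_profile(pt.params, subj.regimen, subj.times,
                                       cov=subj.covariates).concentrations
        preds.append(rows)
    return preds


def _loglik_components(subjects, candidates, error: AssayErrorModel):
    """Gamma-independent pieces of the log likelihood matrix.

    Returns (log_sd_sum, weighted_rss, n_obs) where, for subject i and
    point j, loglik_ij(gamma) =
        -n_i/2 * log(2*pi*gamma) - log_sd_sum_ij - weighted_rss_ij / (2*gamma).
    """
    preds = _prediction_tensor(subjects, candidates)
    n = len(subjects)
    m = len(candidates)
    log_sd_sum = np.empty((n, m))
    weighted_rss = np.empty((n, m))
    n_obs = np.array([len(s.observations) for s in subjects])
    for i, subj in enumerate(subjects):
        sd = np.asarray(error.sd_at(preds[i]))
        res = preds[i] - subj.concentrations[None, :]
        log_sd_sum[i] = np.log(sd).sum(axis=1)
        weighted_rss[i] = ((res / sd) ** 2).sum(axis=1)
    return log_sd_sum, weighted_rss, n_obs


def log_likelihood_matrix(subjects: Sequence[SubjectData],
                          candidates: DiscreteDistribution,
                          error: AssayErrorModel) -> np.ndarray:
    """Matrix of log p(subject i | support point j)."""
    log_sd, wrss, n_obs = _loglik_components(subjects, candidates, error)
    g = error.gamma
    return (-0.5 * n_obs[:, None] * (_LOG_2PI + np.log(g))
            - log_sd - wrss / (2.0 * g))


def likelihood_matrix(subjects, candidates, error: AssayErrorModel) -> np.ndarray:
    """Per-subject likelihoods at each support point.

    Computed in log space; rows whose maximum would underflow a double
    are returned as shifted exponentials (relative likelihoods), which is
    all the EM weight update needs.  Rows that underflow entirely are
    floored at the smallest normal double with a warning.
    """
    ll = log_likelihood_matrix(subjects, candidates, error)
    rowmax = ll.max(axis=1, keepdims=True)
    shift = np.where(rowmax < -600.0, rowmax, 0.0)
    lik = np.exp(ll - shift)
    dead = lik.max(axis=1) <= 0
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} subject(s) unexplainable by every candidate "
            f"point; likelihood floored", RuntimeWarning, stacklevel=2,
        )
        lik[dead] = _TINY
    return lik


def em_weights(lik: np.ndarray, tol: float = 1e-4, max_cycles: int = 1000,
               w0: np.ndarray | None = None, return_trace: bool = False):
    """Multiplicative EM for the NPML mixing weights.

    Returns (weights, log_likelihood, cycles, converged), plus the
    per-cycle log-likelihood trace when ``return_trace`` is set.  The log
    likelihood is computed from the matrix as given (shifted rows yield a
    shifted LL; the shift is constant in w so the optimum is unaffected).
    """
    lik = np.asarray(lik, dtype=float)
    if np.any(lik < 0):
        raise ValueError("likelihood matrix must be non-negative")
    n, m = lik.shape
    w = np.full(m, 1.0 / m) if w0 is None else np.asarray(w0, dtype=float) / np.sum(w0)
    mix = lik @ w
    if np.any(mix <= 0):
        raise ValueError("a subject has zero likelihood under every weighted point")
    ll = float(np.log(mix).sum())
    trace = [ll]
    cycles = 0
    converged = False
    for cycles in range(1, max_cycles + 1):
        w = w * ((lik / mix[:, None]).sum(axis=0) / n)
        w = w / w.sum()
        mix = lik @ w
        ll_new = float(np.log(mix).sum())
        trace.append(ll_new)
        if ll_new - ll < tol:
            ll = max(ll, ll_new)
            converged = True
            break
        ll = ll_new
    if return_trace:
        return w, ll, cycles, converged, np.array(trace)
    return w, ll, cycles, converged


def _sobol_grid(bounds: np.ndarray, n_points: int, seed: int | None) -> np.ndarray:
    """Quasi-random candidates, log-uniform within bounds."""
    sampler = qmc.Sobol(d=bounds.shape[0], scramble=True, seed=seed)
    u = sampler.random(n_points)
    lo, hi = np.log(bounds[:, 0]), np.log(bounds[:, 1])
    return np.exp(lo + u * (hi - lo))


@dataclass
class NPMLResults:
    """Results of a nonparametric population fit."""

    model: "NPMLModel"
    distribution: DiscreteDistribution
    log_likelihood: float
    cycles: int
    converged: bool
    gamma_hat: float
    regression_population: tuple[float, float, float] = field(default=None)  # r2, slope, intercept
    regression_posterior: tuple[float, float, float] = field(default=None)

    @property
    def k(self) -> int:
        """Number of structural parameters in the model kind."""
        return len(param_names(self.model.model_kind))

    @property
    def aic(self) -> float:
        """Akaike information criterion, 2k - 2*LL."""
        return 2.0 * self.k - 2.0 * self.log_likelihood

    def lrt_vs(self, other: "NPMLResults"):
        """Likelihood-ratio comparison with another fit on the same data.

        Returns a dict with the statistic 2*|dLL|, degrees of freedom and
        the chi-square p-value; the p-value is omitted (None) for
        non-nested model kinds.
        """
        stat = 2.0 * abs(self.log_likelihood - other.log_likelihood)
        df = abs(self.k - other.k)
        pair = tuple(sorted((self.model.model_kind, other.model.model_kind),
                            key=lambda kind: len(param_names(kind))))
        nested = (pair in _NESTED or
                  self.model.model_kind == other.model.model_kind)
        p = float(chi2.sf(stat, max(df, 1))) if nested else None
        if nested and df == 0:
            p = 1.0 if stat == 0 else float(chi2.sf(stat, 1))
        return {"statistic": stat, "df": df, "p_value": p, "nested": nested}

    def predictions(self):
        """Pooled (observed, population-predicted, posterior-predicted)."""
        from .posterior import posterior_update  # local import: avoid cycle

        obs, pop_pred, post_pred = [], [], []
        w = self.distribution.probabilities()
        preds = _prediction_tensor(self.model.subjects, self.distribution)
        error = self.model.error.with_gamma(self.gamma_hat)
        for i, subj in enumerate(self.model.subjects):
            obs.extend(subj.concentrations)
            pop_pred.extend(w @ preds[i])
            from .posterior import PatientPast
            past = PatientPast(subj.covariates, subj.regimen, subj.observations)
            post = posterior_update(self.distribution, past, error)
            post_pred.extend(post.probabilities() @ preds[i])
        return np.array(obs), np.array(pop_pred), np.array(post_pred)

    def summary(self) -> str:
        df = self.distribution.summarize()
        lines = [
            "Nonparametric population PK fit",
            "=" * 46,
            f"model kind:        {self.model.model_kind}",
            f"subjects:          {len(self.model.subjects)}",
            f"support points:    {len(self.distribution)}",
            f"log likelihood:    {self.log_likelihood:.3f}",
            f"AIC (2k - 2LL):    {self.aic:.3f}",
            f"EM cycles:         {self.cycles}" + ("" if self.converged else "  (not converged)"),
            f"gamma:             {self.gamma_hat:.4g}",
        ]
        if self.regression_population is not None:
            r2, slope, intercept = self.regression_population
            lines.append(f"obs~pred (population): r2={r2:.3f} slope={slope:.3f} "
                         f"intercept={intercept:.3f}")
        if self.regression_posterior is not None:
            r2, slope, intercept = self.regression_posterior
            lines.append(f"obs~pred (posterior):  r2={r2:.3f} slope={slope:.3f} "
                         f"intercept={intercept:.3f}")
        lines.append("-" * 46)
        lines.append(df.to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


class NPMLModel:
    """Nonparametric population model over a set of subjects.

    Parameters
    ----------
    subjects
        Subject records (covariates, regimen, observations).
    model_kind
        One of ``linear``, ``michaelis_menten``, ``parallel``,
        ``linear_covariate``.
    error
        Assay-error model; its gamma is the starting value when a gamma
        grid is profiled.
    bounds
        (d, 2) array of per-parameter search bounds; required.
    """

    def __init__(self, subjects: Sequence[SubjectData], model_kind: str,
                 error: AssayErrorModel, bounds):
        if len(subjects) < 2:
            raise ValueError("population fitting needs at least 2 subjects")
        self.subjects = tuple(subjects)
        self.model_kind = model_kind
        self.error = error
        self.bounds = np.asarray(bounds, dtype=float)
        if self.bounds.shape != (len(param_names(model_kind)), 2):
            raise ValueError(f"bounds must be ({len(param_names(model_kind))}, 2)")
        if np.any(self.bounds <= 0) or np.any(self.bounds[:, 0] >= self.bounds[:, 1]):
            raise ValueError("bounds must be positive with lo < hi")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, model_kind: str,
                       error: AssayErrorModel, bounds) -> "NPMLModel":
        """Build from a long table.

        Expected columns: patient_id, crcl, weight, record (DOSE/OBS),
        time_h, duration_h, amount_mg, conc_mg_L.
        """
        from .pk import DoseEvent

        subjects = []
        for pid, grp in df.groupby("patient_id", sort=False):
            cov = PatientCovariates(str(pid), float(grp["crcl"].iloc[0]),
                                    float(grp["weight"].iloc[0]))
            doses = [DoseEvent(float(r.time_h), float(r.duration_h), float(r.amount_mg))
                     for r in grp[grp["record"] == "DOSE"].itertuples()]
            obs = sorted((float(r.time_h), float(r.conc_mg_L))
                         for r in grp[grp["record"] == "OBS"].itertuples())
            subjects.append(SubjectData(cov, Regimen(doses), tuple(obs)))
        return cls(subjects, model_kind, error, bounds)

    # -- fitting ----------------------------------------------------------

    def _solve_weights(self, candidates: DiscreteDistribution, gamma: float,
                       tol: float, max_cycles: int):
        log_sd, wrss, n_obs = self._components_cache(candidates)
        ll_mat = (-0.5 * n_obs[:, None] * (_LOG_2PI + np.log(gamma))
                  - log_sd - wrss / (2.0 * gamma))
        rowmax = ll_mat.max(axis=1, keepdims=True)
        lik = np.exp(ll_mat - rowmax)
        lik[lik.max(axis=1) <= 0] = _TINY
        w, ll_shifted, cycles, converged = em_weights(lik, tol=tol, max_cycles=max_cycles)
        return w, ll_shifted + float(rowmax.sum()), cycles, converged

    def _components_cache(self, candidates):
        key = id(candidates)
        if getattr(self, "_cache_key", None) != key:
            self._cache_val = _loglik_components(self.subjects, candidates,
                                                 self.error.with_gamma(1.0))
            self._cache_key = key
        return self._cache_val

    def fit(self, grid_size: int = 512, seed: int | None = None,
            refine: bool = True, gamma_grid: Sequence[float] | None = None,
            tol: float = 1e-4, max_cycles: int = 1000,
            max_refine_rounds: int = 6, prune_tol: float = 1e-9,
            compute_regressions: bool = True) -> NPMLResults:
        """Estimate the nonparametric population distribution.

        A quasi-random (Sobol, log-uniform) grid of ``grid_size``
        candidates is laid within the bounds and solved by EM; when
        ``refine`` is on, surviving points (probability > 1e-6) are
        perturbed +/-20% axis-wise and the enlarged candidate set
        re-solved until the log-likelihood gain drops below ``tol``.
        ``gamma_grid`` profiles the variance scalar over a coarse grid,
        keeping the gamma with the best final likelihood.
        """
        grid = _sobol_grid(self.bounds, grid_size, seed)
        gammas = list(gamma_grid) if gamma_grid is not None else [self.error.gamma]

        best = None
        for gamma in gammas:
            cand = DiscreteDistribution.from_matrix(
                grid, np.full(len(grid), 1.0 / len(grid)), self.model_kind)
            w, ll, cycles, converged = self._solve_weights(cand, gamma, tol, max_cycles)
            total_cycles = cycles
            if refine:
                for _ in range(max_refine_rounds):
                    keep = w > 1e-6
                    base = cand.params_matrix()[keep]
                    perturbed = [base]
                    for j in range(base.shape[1]):
                        for f in (0.8, 1.2):
                            pt = base.copy()
                            pt[:, j] = np.clip(pt[:, j] * f,
                                               self.bounds[j, 0], self.bounds[j, 1])
                            perturbed.append(pt)
                    new_mat = np.unique(np.vstack(perturbed), axis=0)
                    new_cand = DiscreteDistribution.from_matrix(
                        new_mat, np.full(len(new_mat), 1.0 / len(new_mat)),
                        self.model_kind)
                    w2, ll2, cycles2, conv2 = self._solve_weights(
                        new_cand, gamma, tol, max_cycles)
                    total_cycles += cycles2
                    if ll2 > ll:
                        cand, w, converged = new_cand, w2, conv2
                        gain, ll = ll2 - ll, ll2
                        if gain < tol:
                            break
                    else:
                        break
            if best is None or ll > best[1]:
                best = (cand, ll, w, total_cycles, converged, gamma)

        cand, ll, w, cycles, converged, gamma = best
        keep = w > prune_tol
        dist = DiscreteDistribution.from_matrix(
            cand.params_matrix()[keep], w[keep], self.model_kind)
        res = NPMLResults(self, dist, ll, cycles, converged, gamma)
        if compute_regressions:
            from .evaluate import regression_stats
            obs, pop, post = res.predictions()
            try:
                res.regression_population = regression_stats(obs, pop)
                res.regression_posterior = regression_stats(obs, post)
            except ValueError:
                pass  # degenerate predictions; regressions stay unset
        return res


def fit_population(subjects, model_kind: str, initial_grid_size: int,
                   error: AssayErrorModel, bounds, seed: int | None = None,
                   refine: bool = True, **kwargs) -> NPMLResults:
    """Functional wrapper over ``NPMLModel(...).fit(...)``."""
    model = NPMLModel(subjects, model_kind, error, bounds)
    return model.fit(grid_size=initial_grid_size, seed=seed, refine=refine, **kwargs)
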