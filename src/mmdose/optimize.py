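"""Multiple-model dose selection over the Bayesian posterior.

The controller picks the single amount, shared by all planned future
infusions, that minimizes the expected weighted squared error between
model-predicted and clinician-specified target concentrations, the
expectation running over the patient's discrete posterior:

    J(dose) = sum_i p_i * sum_j lambda_j * (C_pred(i, dose, t_j) - T_j)^2

Residual drug from the dosing history is carried into every prediction.
For linear disposition the prediction is affine in dose, making J a
quadratic with a closed-form minimizer; saturable kinds fall back to
bounded scalar search.  The same machinery run with *observed* (rather
than desired) concentrations as targets inverts the problem and
estimates the dose that must have produced them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .assay import AssayErrorModel
from .pk import DoseEvent, Regimen, simulate_profile
from .posterior import PatientPast
from .prior import DiscreteDistribution


class FlatObjectiveError(RuntimeError):
    """No target is sensitive to the dose; the optimum is undefined."""


@dataclass(frozen=True)
class TargetSpec:
    """Timed concentration targets.

    Each entry is (time h, concentration mg/L, weight); a weight of None
    defers to the assay-information default 1/(gamma*SD(T)^2).
    """

    targets: tuple[tuple[float, float, float | None], ...]

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("at least one target is required")
        for t, c, lam in self.targets:
            if lam is not None and lam < 0:
                raise ValueError(f"negative target weight at t={t}")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _, _ in self.targets])

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for _, c, _ in self.targets])

    def resolved_weights(self, error: AssayErrorModel) -> np.ndarray:
        return np.array([
            error.weight_at(c) if lam is None else lam
            for _, c, lam in self.targets
        ])


@dataclass(frozen=True)
class FutureTemplate:
    """Planned future infusions with a common, to-be-chosen amount."""

    dose_times: tuple[float, ...]
    durations: tuple[float, ...]
    dose_bounds: tuple[float, float] = (100.0, 20000.0)
    dose_grid_step: float = 10.0

    def __post_init__(self) -> None:
        if len(self.dose_times) != len(self.durations):
            raise ValueError("dose_times and durations must have equal length")
        if not self.dose_times:
            raise ValueError("template needs at least one future dose")
        lo, hi = self.dose_bounds
        if not (0 < lo < hi):
            raise ValueError(f"invalid dose bounds {self.dose_bounds}")

    def regimen(self, dose: float) -> Regimen:
        return Regimen(tuple(DoseEvent(t, d, dose)
                             for t, d in zip(self.dose_times, self.durations)))


@dataclass(frozen=True)
class DoseRecommendation:
    """A selected dose and its expected performance at the targets."""

    dose: float                  # exact optimizer output, mg
    dose_practical: float        # rounded to 10 mg for prescribing
    expected_wsse: float         # mg^2/L^2 at the exact dose
    achieved_targets: np.ndarray  # posterior-mean prediction at target times
    target_times: np.ndarray
    target_concentrations: np.ndarray
    clipped: bool                # optimum lay outside the dose bounds

    def summary(self) -> str:
        lines = [
            "Dose recommendation",
            "=" * 40,
            f"dose:              {self.dose:.1f} mg"
            + ("  (clipped to bounds)" if self.clipped else ""),
            f"practical dose:    {self.dose_practical:.0f} mg",
            f"expected WSSE:     {self.expected_wsse:.4g} mg^2/L^2",
            "targets (t, goal -> predicted):",
        ]
        for t, goal, got in zip(self.target_times, self.target_concentrations,
                                self.achieved_targets):
            lines.append(f"  {t:8.2f} h  {goal:8.2f} -> {got:8.2f} mg/L")
        return "\n".join(lines)


def _linear_kind(post: DiscreteDistribution) -> bool:
    return post.model_kind in ("linear", "linear_covariate")


def _predictions(post, past, template, dose, times) -> np.ndarray:
    """(n_points, n_targets) predicted concentrations at `times`."""
    full = past.regimen + template.regimen(dose)
    out = np.empty((len(post), len(times)))
    for j, pt in enumerate(post.points):
        out[j] = simulate_profile(pt.params, full, times,
                                  cov=past.covariates).concentrations
    return out


def _affine_parts(post, past, template, times):
    """base + dose*unit decomposition, valid for linear kinds."""
    base = np.empty((len(post), len(times)))
    unit = np.empty((len(post), len(times)))
    unit_reg = template.regimen(1.0)
    for j, pt in enumerate(post.points):
        base[j] = simulate_profile(pt.params, past.regimen, times,
                                   cov=past.covariates).concentrations
        unit[j] = simulate_profile(pt.params, unit_reg, times,
                                   cov=past.covariates).concentrations
    return base, unit


def expected_wsse(post: DiscreteDistribution, past: PatientPast,
                  template: FutureTemplate, dose: float, targets: TargetSpec,
                  error: AssayErrorModel | None = None,
                  weights: Sequence[float] | None = None) -> float:
    """Posterior-expected weighted squared error at a candidate dose."""
    lam = _resolve_weights(targets, error, weights)
    pred = _predictions(post, past, template, dose, targets.times)
    res = pred - targets.concentrations[None, :]
    return float(post.probabilities() @ ((res**2) @ lam))


def _resolve_weights(targets, error, weights):
    if weights is not None:
        lam = np.asarray(weights, dtype=float)
        if lam.shape != (len(targets.targets),):
            raise ValueError("weights length must match targets")
        return lam
    return targets.resolved_weights(error or AssayErrorModel())


def optimize_dose(post: DiscreteDistribution, past: PatientPast,
                  template: FutureTemplate, targets: TargetSpec,
                  error: AssayErrorModel | None = None,
                  weights: Sequence[float] | None = None) -> DoseRecommendation:
    """Select the future dose minimizing the expected weighted squared error.

    Linear kinds use the closed-form quadratic minimizer (prediction is
    affine in dose); saturable kinds a bounded Brent search with absolute
    tolerance ``template.dose_grid_step``.  An optimum outside the dose
    bounds is clipped and flagged.
    """
    lam = _resolve_weights(targets, error, weights)
    if not np.any(lam > 0):
        raise FlatObjectiveError("all target weights are zero")
    lo, hi = template.dose_bounds
    times = targets.times
    w = post.probabilities()
    tgt = targets.concentrations

    if _linear_kind(post):
        base, unit = _affine_parts(post, past, template, times)
        denom = float(w @ ((unit**2) @ lam))
        if denom <= 0 or not math.isfinite(denom):
            raise FlatObjectiveError(
                "targets are insensitive to the dose (no future-dose signal "
                "at any target time)"
            )
        numer = float(w @ ((unit * (tgt[None, :] - base)) @ lam))
        opt = numer / denom
    else:
        probe = expected_wsse(post, past, template, lo, targets, error, lam)
        probe_hi = expected_wsse(post, past, template, hi, targets, error, lam)
        res = minimize_scalar(
            lambda d: expected_wsse(post, past, template, d, targets, error, lam),
            bounds=(lo, hi), method="bounded",
            options={"xatol": template.dose_grid_step},
        )
        opt = float(res.x)
        if abs(probe - probe_hi) < 1e-12 and abs(probe - res.fun) < 1e-12:
            raise FlatObjectiveError("objective is flat over the dose bounds")

    clipped = not (lo <= opt <= hi)
    dose = min(max(opt, lo), hi)
    wsse = expected_wsse(post, past, template, dose, targets, error, lam)
    achieved = post.probabilities() @ _predictions(post, past, template, dose, times)
    return DoseRecommendation(
        dose=dose,
        dose_practical=round(dose / 10.0) * 10.0,
        expected_wsse=wsse,
        achieved_targets=achieved,
        target_times=times,
        target_concentrations=tgt,
        clipped=clipped,
    )


def estimate_delivered_dose(post: DiscreteDistribution, past: PatientPast,
                            template: FutureTemplate,
                            observed_as_targets: TargetSpec,
                            reference_dose: float | None = None,
                            error: AssayErrorModel | None = None,
                            weights: Sequence[float] | None = None):
    """Estimate the dose that produced later observed concentrations.

    Identical computation to ``optimize_dose`` with the observations used
    as targets.  Returns (recommendation, percent_deviation), the latter
    100*(estimated - reference)/reference when a reference dose is given.
    """
    rec = optimize_dose(post, past, template, observed_as_targets,
                        error=error, weights=weights)
    pct = None
    if reference_dose is not None:
        if reference_dose <= 0:
            raise ValueError("reference dose must be positive")
        pct = 100.0 * (rec.dose - reference_dose) / reference_dose
    return rec, pct
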