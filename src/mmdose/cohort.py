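"""Virtual-patient generator for in-silico validation of the dosing loop.

Emulates the study conditions the method assumes: covariates drawn
uniformly over the pooled critically ill cohort's ranges, true PK
parameters drawn from the discrete population distribution, and
observations perturbed by assay noise following the SD polynomial.
Canonical TDM sampling designs (1, 2, 3 or 6 samples within the first
dosing interval) are provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assay import AssayErrorModel
from .pk import ModelParameters, PatientCovariates, Regimen, simulate_profile
from .posterior import PatientPast
from .prior import DiscreteDistribution
from .reference import CRCL_RANGE_ML_MIN, WEIGHT_RANGE_KG

# Floor for noisy observations (assay lower-limit stand-in), mg/L.
_OBS_FLOOR = 0.01

# Canonical sampling times (h after start of the first dose) by design size.
_SCHEDULES = {
    1: (6.0,),
    2: (0.5, 6.0),
    3: (0.5, 3.0, 6.0),
    6: (0.5, 1.0, 2.0, 3.0, 4.0, 6.0),
}


def cockcroft_gault(age: float, weight: float, serum_creatinine: float,
                    sex: str) -> float:
    """Estimated creatinine clearance (mL/min).

    (140 - age) * weight / (72 * Scr), times 0.85 for females.  Age in
    years, weight in kg, serum creatinine in mg/dL.
    """
    if age <= 0 or weight <= 0 or serum_creatinine <= 0:
        raise ValueError("age, weight and serum creatinine must be positive")
    if age >= 140:
        raise ValueError("age must be below 140 years")
    sex = sex.lower()
    if sex not in ("male", "female", "m", "f"):
        raise ValueError(f"sex must be male or female, got {sex!r}")
    crcl = (140.0 - age) * weight / (72.0 * serum_creatinine)
    if sex in ("female", "f"):
        crcl *= 0.85
    return crcl


def tdm_schedule(design: int) -> list[float]:
    """Sampling times for the 1-, 2-, 3- or 6-observation TDM designs."""
    try:
        return list(_SCHEDULES[design])
    except KeyError:
        raise ValueError(f"design must be one of {sorted(_SCHEDULES)}, got {design}") from None


def sample_covariates(n: int, seed: int | None = None,
                      crcl_range: tuple[float, float] = CRCL_RANGE_ML_MIN,
                      weight_range: tuple[float, float] = WEIGHT_RANGE_KG,
                      id_prefix: str = "sim") -> list[PatientCovariates]:
    """Uniform covariate draws within the cohort ranges (deterministic per seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    for lo, hi in (crcl_range, weight_range):
        if lo > hi:
            raise ValueError(f"invalid range ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    crcl = rng.uniform(*crcl_range, size=n) if crcl_range[0] < crcl_range[1] \
        else np.full(n, crcl_range[0])
    wt = rng.uniform(*weight_range, size=n) if weight_range[0] < weight_range[1] \
        else np.full(n, weight_range[0])
    return [PatientCovariates(f"{id_prefix}{i + 1:03d}", float(c), float(w))
            for i, (c, w) in enumerate(zip(crcl, wt))]


@dataclass(frozen=True)
class SimulatedPatient:
    truth: ModelParameters
    past: PatientPast
    true_concentrations: np.ndarray


def generate_patient(prior: DiscreteDistribution, cov: PatientCovariates,
                     regimen: Regimen, schedule, error: AssayErrorModel,
                     seed: int | None = None) -> SimulatedPatient:
    """Draw one virtual patient and their noisy TDM observations.

    The true parameter vector is one prior support point sampled by its
    probability; observations are the true concentrations at the schedule
    times plus independent normal noise with SD equal to the observation
    SD at the *true* concentration, floored at 0.01 mg/L.
    """
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size == 0:
        raise ValueError("schedule must contain at least one sampling time")
    if schedule.min() < 0 or np.any(np.diff(schedule) < 0):
        raise ValueError("schedule times must be non-negative and sorted")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(prior), p=prior.probabilities())
    truth = prior.points[idx].params
    true_c = simulate_profile(truth, regimen, schedule, cov=cov).concentrations
    sd = np.sqrt(np.asarray(error.obs_variance(true_c), dtype=float))
    noisy = np.maximum(true_c + rng.normal(0.0, 1.0, size=true_c.size) * sd,
                       _OBS_FLOOR)
    past = PatientPast(cov, regimen, tuple(zip(schedule.tolist(), noisy.tolist())))
    return SimulatedPatient(truth, past, true_c)


def generate_cohort(prior: DiscreteDistribution, n: int, regimen: Regimen,
                    schedule, error: AssayErrorModel,
                    seed: int | None = None, **covariate_kwargs) -> list[SimulatedPatient]:
    """A cohort of virtual patients with per-patient derived seeds."""
    rng = np.random.default_rng(seed)
    covs = sample_covariates(n, seed=int(rng.integers(2**31)), **covariate_kwargs)
    return [
        generate_patient(prior, cov, regimen, schedule, error,
                         seed=int(rng.integers(2**31)))
        for cov in covs
    ]
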