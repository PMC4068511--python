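"""Two-compartment structural PK models under piecewise-constant infusion.

Four disposition variants are supported, differing in how drug leaves the
central compartment and whether patient covariates enter:

* ``linear`` — first-order elimination (clearance ``cl``),
* ``michaelis_menten`` — saturable elimination (``vmax``, ``km``),
* ``parallel`` — first-order plus saturable elimination in parallel,
* ``linear_covariate`` — first-order elimination with clearance linear in
  estimated creatinine clearance and central volume linear in body weight.

State is drug amount (mg) in the central (``x1``) and peripheral (``x2``)
compartments; the observed quantity is the central concentration
``x1 / vc`` in mg/L.  Dosing is zero-order infusion only: a "bolus" is a
short infusion of its stated duration.  Time runs in hours from the start
of the first dose, and the concentration at an infusion-start instant is
the left limit (the infusion has contributed nothing yet).

Linear variants are solved in closed form segment-by-segment (Putzer's
form of the 2x2 matrix exponential under constant input); the saturable
variants use a stiff-capable adaptive integrator with breakpoints inserted
at every infusion start/stop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp


class InvalidParameterError(ValueError):
    """A parameter vector violates its model's constraints."""


class SimulationError(RuntimeError):
    """The numerical integrator failed or produced unusable output."""


class ConvergenceError(RuntimeError):
    """An iterative computation did not converge within its cap."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientCovariates:
    """Covariates entering the covariate-linear model.

    crcl is the Cockcroft-Gault estimated creatinine clearance (mL/min),
    weight the total body weight (kg).
    """

    patient_id: str
    crcl: float
    weight: float

    def __post_init__(self) -> None:
        if not (self.crcl > 0 and self.weight > 0):
            raise InvalidParameterError(
                f"covariates must be positive (crcl={self.crcl}, weight={self.weight})"
            )


@dataclass(frozen=True)
class DoseEvent:
    """One zero-order infusion: start time (h), duration (h), amount (mg)."""

    start: float
    duration: float
    amount: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InvalidParameterError(f"infusion duration must be > 0, got {self.duration}")
        if self.amount < 0:
            raise InvalidParameterError(f"dose amount must be >= 0, got {self.amount}")
        if self.start < 0:
            raise InvalidParameterError(f"dose start must be >= 0, got {self.start}")

    @property
    def rate(self) -> float:
        """Infusion rate in mg/h."""
        return self.amount / self.duration

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class Regimen:
    """An ordered collection of infusions; overlapping rates add."""

    doses: tuple[DoseEvent, ...]

    def __init__(self, doses: Sequence[DoseEvent] = ()):
        object.__setattr__(self, "doses", tuple(sorted(doses, key=lambda d: d.start)))

    def __add__(self, other: "Regimen") -> "Regimen":
        return Regimen(self.doses + other.doses)

    def scaled(self, factor: float) -> "Regimen":
        return Regimen(tuple(DoseEvent(d.start, d.duration, d.amount * factor) for d in self.doses))

    def shifted(self, offset: float) -> "Regimen":
        return Regimen(tuple(DoseEvent(d.start + offset, d.duration, d.amount) for d in self.doses))

    @property
    def horizon(self) -> float:
        """End of the last infusion (0 for an empty regimen)."""
        return max((d.end for d in self.doses), default=0.0)

    def total_amount(self) -> float:
        return sum(d.amount for d in self.doses)

    def rate_breakpoints(self) -> np.ndarray:
        """Sorted unique times at which the total infusion rate changes."""
        pts = {0.0}
        for d in self.doses:
            pts.add(d.start)
            pts.add(d.end)
        return np.array(sorted(pts))

    def rate_at(self, t: float) -> float:
        """Total infusion rate on the segment to the *right* of t (mg/h)."""
        return sum(d.rate for d in self.doses if d.start <= t < d.end)


def repeated_doses(amount: float, interval: float, duration: float,
                   n_doses: int, first_start: float = 0.0) -> Regimen:
    """A regimen of n identical infusions every `interval` hours."""
    return Regimen(tuple(
        DoseEvent(first_start + k * interval, duration, amount) for k in range(n_doses)
    ))


@dataclass(frozen=True)
class ConcentrationProfile:
    """Central-compartment concentrations (mg/L) at the given times (h)."""

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.shape != c.shape:
            raise ValueError("times and concentrations must have equal length")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)


def _require_positive(obj, names: Sequence[str]) -> None:
    for name in names:
        v = getattr(obj, name)
        if not (v > 0) or not math.isfinite(v):
            raise InvalidParameterError(f"{type(obj).__name__}.{name} must be finite and > 0, got {v}")


@dataclass(frozen=True)
class LinearParams:
    """First-order elimination: cl (L/h), vc (L), kcp, kpc (1/h)."""

    cl: float
    vc: float
    kcp: float
    kpc: float

    model_kind = "linear"

    def __post_init__(self) -> None:
        _require_positive(self, ("cl", "vc", "kcp", "kpc"))


@dataclass(frozen=True)
class MMParams:
    """Michaelis-Menten elimination: vmax (mg/h), km (mg/L), vc, kcp, kpc."""

    vmax: float
    km: float
    vc: float
    kcp: float
    kpc: float

    model_kind = "michaelis_menten"

    def __post_init__(self) -> None:
        _require_positive(self, ("vmax", "km", "vc", "kcp", "kpc"))


@dataclass(frozen=True)
class ParallelParams:
    """Parallel first-order and Michaelis-Menten elimination."""

    cl: float
    vmax: float
    km: float
    vc: float
    kcp: float
    kpc: float

    model_kind = "parallel"

    def __post_init__(self) -> None:
        _require_positive(self, ("cl", "vmax", "km", "vc", "kcp", "kpc"))


@dataclass(frozen=True)
class CovariateLinearParams:
    """First-order elimination with covariates.

    Effective clearance is ``cl_i + cl_s * crcl`` (cl_s in L/h per mL/min)
    and effective central volume ``v_i + v_s * weight`` (v_s in L/kg).
    Individual components may be zero but the effective values must be
    positive for the patient at hand.
    """

    cl_i: float
    cl_s: float
    v_i: float
    v_s: float
    kcp: float
    kpc: float

    model_kind = "linear_covariate"

    def __post_init__(self) -> None:
        for name in ("cl_i", "cl_s", "v_i", "v_s"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise InvalidParameterError(f"CovariateLinearParams.{name} must be >= 0, got {v}")
        _require_positive(self, ("kcp", "kpc"))


ModelParameters = LinearParams | MMParams | ParallelParams | CovariateLinearParams

PARAM_CLASSES = {
    "linear": LinearParams,
    "michaelis_menten": MMParams,
    "parallel": ParallelParams,
    "linear_covariate": CovariateLinearParams,
}


def param_names(model_kind: str) -> tuple[str, ...]:
    """Field names (and order) of the parameter vector for a model kind."""
    return tuple(f.name for f in fields(PARAM_CLASSES[model_kind]))


def params_from_vector(model_kind: str, vector: Sequence[float]) -> ModelParameters:
    return PARAM_CLASSES[model_kind](*[float(v) for v in vector])


def params_to_vector(params: ModelParameters) -> np.ndarray:
    return np.array([getattr(params, f.name) for f in fields(params)], dtype=float)


def effective_disposition(params: CovariateLinearParams,
                          cov: PatientCovariates) -> tuple[float, float]:
    """Map covariates to the patient's effective clearance and volume.

    Returns (cl, vc) with cl = cl_i + cl_s*crcl (L/h) and
    vc = v_i + v_s*weight (L).  Raises if either comes out nonpositive.
    """
    cl = params.cl_i + params.cl_s * cov.crcl
    vc = params.v_i + params.v_s * cov.weight
    if cl <= 0 or vc <= 0:
        raise InvalidParameterError(
            f"effective disposition nonpositive: cl={cl}, vc={vc} for {cov.patient_id}"
        )
    return cl, vc


# ---------------------------------------------------------------------------
# Simulation engine
# ---------------------------------------------------------------------------

def _resolve(params: ModelParameters, cov: PatientCovariates | None):
    """Return (kind, cl, vmax, km, vc, kcp, kpc) with covariates applied.

    cl is None for the pure Michaelis-Menten kind; vmax/km are None for
    linear kinds.
    """
    if isinstance(params, LinearParams):
        return ("linear", params.cl, None, None, params.vc, params.kcp, params.kpc)
    if isinstance(params, CovariateLinearParams):
        if cov is None:
            raise InvalidParameterError("covariate-linear model requires patient covariates")
        cl, vc = effective_disposition(params, cov)
        return ("linear", cl, None, None, vc, params.kcp, params.kpc)
    if isinstance(params, MMParams):
        return ("mm", None, params.vmax, params.km, params.vc, params.kcp, params.kpc)
    if isinstance(params, ParallelParams):
        return ("mm", params.cl, params.vmax, params.km, params.vc, params.kcp, params.kpc)
    raise InvalidParameterError(f"unknown parameter type {type(params)!r}")


def _segment_linear(ke: float, kcp: float, kpc: float, rate: float,
                    x0: np.ndarray, taus: np.ndarray) -> np.ndarray:
    """States at elapsed times `taus` under constant input `rate`.

    Putzer form of exp(A*tau) for the 2x2 system
    A = [[-(ke+kcp), kpc], [kcp, -kpc]], with the forced response
    integral handled so that ke -> 0 (no elimination) stays finite.
    Returns an array of shape (len(taus), 2).
    """
    s = ke + kcp + kpc
    p = ke * kpc
    disc = s * s - 4.0 * p
    if disc < 1e-24:  # numerically repeated eigenvalues: nudge
        disc = 1e-24
    rt = math.sqrt(disc)
    l1 = 0.5 * (-s + rt)
    l2 = 0.5 * (-s - rt)
    a11, a12, a21, a22 = -(ke + kcp), kpc, kcp, -kpc

    taus = np.asarray(taus, dtype=float)
    e1 = np.exp(l1 * taus)
    e2 = np.exp(l2 * taus)
    q = (e1 - e2) / (l1 - l2)
    # Phi = e1*I + q*(A - l1*I)
    p11 = e1 + q * (a11 - l1)
    p12 = q * a12
    p21 = q * a21
    p22 = e1 + q * (a22 - l1)

    # Psi = int_0^tau Phi(s) ds, elementwise via I1, I2; l1 -> 0 in the
    # no-elimination limit, l2 < 0 always (kcp, kpc > 0)
    if abs(l1) > 1e-14:
        i1 = (e1 - 1.0) / l1
    else:
        i1 = taus.astype(float)
    i2 = (e2 - 1.0) / l2
    j = (i1 - i2) / (l1 - l2)
    s11 = i1 + j * (a11 - l1)
    s21 = j * a21

    x1 = p11 * x0[0] + p12 * x0[1] + rate * s11
    x2 = p21 * x0[0] + p22 * x0[1] + rate * s21
    return np.stack([x1, x2], axis=-1)


def _simulate_states(kind: str, cl, vmax, km, vc, kcp, kpc,
                     regimen: Regimen, times: np.ndarray,
                     x0: Sequence[float] = (0.0, 0.0),
                     rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    """States (n, 2) at requested times, x0 given at t=0.

    Boundary times take the left limit: a time equal to a rate breakpoint
    is evaluated within the preceding segment.
    """
    times = np.asarray(times, dtype=float)
    if times.size and (times[0] < 0 or np.any(np.diff(times) < 0)):
        raise ValueError("times must be non-negative and sorted")
    t_end = float(times[-1]) if times.size else 0.0
    bps = regimen.rate_breakpoints()
    bps = np.unique(np.concatenate([bps[bps < t_end], [0.0, t_end]]))
    out = np.empty((times.size, 2))
    x = np.array(x0, dtype=float)
    for seg_start, seg_end in zip(bps[:-1], bps[1:]):
        rate = regimen.rate_at(seg_start)
        # left-limit convention: t == seg_start belongs to the previous
        # segment, t == seg_end to this one
        mask = (times > seg_start) & (times <= seg_end)
        taus = times[mask] - seg_start
        if kind == "linear":
            ke = cl / vc
            if taus.size:
                out[mask] = _segment_linear(ke, kcp, kpc, rate, x, taus)
            x = _segment_linear(ke, kcp, kpc, rate, x, np.array([seg_end - seg_start]))[0]
        else:
            def rhs(_t, y):
                c = y[0] / vc
                elim = vmax * c / (km + c)
                if cl is not None:
                    elim += (cl / vc) * y[0]
                return [rate - elim - kcp * y[0] + kpc * y[1],
                        kcp * y[0] - kpc * y[1]]

            t_eval = np.concatenate([taus, [seg_end - seg_start]])
            t_eval = np.unique(t_eval)
            sol = solve_ivp(rhs, (0.0, seg_end - seg_start), x, method="LSODA",
                            t_eval=t_eval, rtol=rtol, atol=atol)
            if not sol.success:
                raise SimulationError(
                    f"integrator failed on segment [{seg_start}, {seg_end}]: {sol.message}"
                )
            if taus.size:
                idx = np.searchsorted(sol.t, taus)
                out[mask] = sol.y[:, idx].T
            x = sol.y[:, -1]
    out[times <= 0] = np.array(x0, dtype=float)
    return out


def simulate_profile(params: ModelParameters, regimen: Regimen,
                     times: Sequence[float],
                     cov: PatientCovariates | None = None) -> ConcentrationProfile:
    """Simulate the central-compartment concentration-time profile.

    The system starts drug-free (x1 = x2 = 0 at t = 0).  Linear kinds use
    the closed-form piecewise solution; saturable kinds a stiff-capable
    integrator (rtol 1e-8, atol 1e-10 mg) with breakpoints at every
    infusion start/stop.
    """
    times = np.asarray(times, dtype=float)
    if not regimen.doses:
        return ConcentrationProfile(times, np.zeros_like(times))
    kind, cl, vmax, km, vc, kcp, kpc = _resolve(params, cov)
    states = _simulate_states(kind, cl, vmax, km, vc, kcp, kpc, regimen, times)
    conc = states[:, 0] / vc
    if np.any(conc < -1e-6):
        raise SimulationError(f"negative concentration beyond tolerance: min {conc.min():.3g} mg/L")
    return ConcentrationProfile(times, np.clip(conc, 0.0, None))


def steady_state_trough(params: ModelParameters, dose: float, interval: float,
                        infusion_duration: float,
                        cov: PatientCovariates | None = None,
                        rel_tol: float = 1e-3, max_doses: int = 500) -> float:
    """Predose (trough) concentration at steady state for repeated dosing.

    Linear kinds solve the periodic fixed point exactly; saturable kinds
    simulate dose after dose until successive troughs agree to ``rel_tol``
    (default 0.1%), raising ``ConvergenceError`` past ``max_doses``.
    """
    if interval <= infusion_duration:
        raise ValueError("dosing interval must exceed the infusion duration")
    if dose == 0:
        return 0.0
    kind, cl, vmax, km, vc, kcp, kpc = _resolve(params, cov)
    one = Regimen((DoseEvent(0.0, infusion_duration, dose),))
    if kind == "linear":
        # one-interval affine map x_end = M x0 + f; steady predose state
        # solves (I - M) x = f
        f = _simulate_states(kind, cl, vmax, km, vc, kcp, kpc, one,
                             np.array([interval]))[0]
        cols = []
        zero = Regimen(())
        for basis in ((1.0, 0.0), (0.0, 1.0)):
            cols.append(_simulate_states(kind, cl, vmax, km, vc, kcp, kpc, zero,
                                         np.array([interval]), x0=basis)[0])
        m = np.column_stack(cols)
        x_star = np.linalg.solve(np.eye(2) - m, f)
        return float(x_star[0] / vc)
    x = np.zeros(2)
    prev = None
    for _ in range(max_doses):
        x = _simulate_states(kind, cl, vmax, km, vc, kcp, kpc, one,
                             np.array([interval]), x0=x)[0]
        trough = x[0] / vc
        if prev is not None and abs(trough - prev) <= rel_tol * max(trough, 1e-12):
            return float(trough)
        prev = trough
    raise ConvergenceError(f"troughs not settled after {max_doses} doses")
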