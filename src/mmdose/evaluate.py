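"""Performance statistics for predicted vs observed concentrations.

Conventions: prediction error is ``pred - obs`` so over-prediction gives
positive bias; "bias" is the weighted mean prediction error (mg/L) and
"precision" the bias-adjusted weighted mean squared prediction error
(mg^2/L^2), with normalized Fisher-information (inverse assay variance)
weights.  ``ft_above_mic`` computes the beta-lactam efficacy index: the
fraction of a dosing interval the concentration spends above the MIC.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import linregress

from .assay import AssayErrorModel
from .pk import ConcentrationProfile


def regression_stats(observed, predicted) -> tuple[float, float, float]:
    """OLS of observed on predicted: returns (r2, slope, intercept)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size < 3:
        raise ValueError("need at least 3 pairs for regression")
    if np.ptp(predicted) == 0:
        raise ValueError("predicted values have zero variance; slope undefined")
    fit = linregress(predicted, observed)
    return float(fit.rvalue**2), float(fit.slope), float(fit.intercept)


def bias_precision(observed, predicted,
                   error: AssayErrorModel | None = None,
                   weights=None) -> tuple[float, float]:
    """Weighted bias (mg/L) and bias-adjusted precision (mg^2/L^2).

    Weights default to assay-information weights 1/(gamma*SD(pred)^2)
    and are normalized to sum to one, keeping bias in concentration
    units.  Explicit ``weights`` override the assay model.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size == 0:
        raise ValueError("need at least one pair")
    if weights is None:
        w = np.asarray((error or AssayErrorModel()).weight_at(predicted), dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    pe = predicted - observed
    bias = float(w @ pe)
    precision = float(w @ pe**2 - bias**2)
    return bias, max(precision, 0.0)


def ft_above_mic(profile: ConcentrationProfile, mic: float,
                 interval: tuple[float, float],
                 fraction_unbound: float = 1.0) -> float:
    """Fraction of [t0, t1] with (free) concentration above the MIC.

    Crossing times are located by linear interpolation between profile
    points; ``fraction_unbound`` scales total to free concentration
    (default 1.0: totals, matching total-concentration targets).
    """
    t0, t1 = interval
    if t1 <= t0:
        raise ValueError("interval end must exceed start")
    t = np.asarray(profile.times, dtype=float)
    c = np.asarray(profile.concentrations, dtype=float) * fraction_unbound
    mask = (t >= t0) & (t <= t1)
    if mask.sum() < 100:
        warnings.warn(
            f"only {int(mask.sum())} profile points inside the interval; "
            f"fT>MIC may be coarse", RuntimeWarning, stacklevel=2,
        )
    t, c = t[mask], c[mask]
    if t.size < 2:
        raise ValueError("profile does not cover the interval")
    above = 0.0
    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        if dt == 0:
            continue
        a, b = c[i] - mic, c[i + 1] - mic
        if a > 0 and b > 0:
            above += dt
        elif a > 0 or b > 0:  # one crossing inside the segment
            frac = abs(a) / (abs(a) + abs(b))
            above += dt * (frac if a > 0 else 1.0 - frac)
    return above / (t[-1] - t[0])
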