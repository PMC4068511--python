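"""Discrete support-point representation of the population distribution.

The nonparametric population distribution is a finite set of support
points — candidate parameter vectors, each carrying a probability.  The
same object serves as the Bayesian prior (population weights) and, after
per-patient reweighting, the posterior: support locations never move,
only the probabilities change.

When only marginal summary statistics are published (means and SDs per
parameter), ``from_moments`` reconstructs a usable prior from independent
truncated log-normal marginals, moment-matched and rescaled so the
realized probability-weighted means hit the targets.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pk import (ModelParameters, PARAM_CLASSES, param_names, params_from_vector,
                 params_to_vector)

_PROB_TOL = 1e-10


class DensityFormatError(ValueError):
    """A density file is malformed."""


@dataclass(frozen=True)
class SupportPoint:
    params: ModelParameters
    probability: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0 + 1e-12):
            raise ValueError(f"probability out of [0, 1]: {self.probability}")


class DiscreteDistribution:
    """A discrete distribution over parameter vectors of one model kind."""

    def __init__(self, points: Sequence[SupportPoint], model_kind: str,
                 bounds: np.ndarray | None = None):
        if not points:
            raise ValueError("a discrete distribution needs at least one support point")
        if model_kind not in PARAM_CLASSES:
            raise ValueError(f"unknown model kind {model_kind!r}")
        cls = PARAM_CLASSES[model_kind]
        for pt in points:
            if not isinstance(pt.params, cls):
                raise ValueError(
                    f"support point of type {type(pt.params).__name__} in a "
                    f"{model_kind} distribution"
                )
        self.points = tuple(points)
        self.model_kind = model_kind
        self.bounds = None if bounds is None else np.asarray(bounds, dtype=float)
        total = float(sum(pt.probability for pt in self.points))
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(f"probabilities sum to {total}, not 1")
        if self.bounds is not None:
            mat = self.params_matrix()
            lo, hi = self.bounds[:, 0], self.bounds[:, 1]
            if np.any(mat < lo - 1e-12) or np.any(mat > hi + 1e-12):
                raise ValueError("support points violate the stated bounds")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return param_names(self.model_kind)

    def probabilities(self) -> np.ndarray:
        return np.array([pt.probability for pt in self.points])

    def params_matrix(self) -> np.ndarray:
        return np.vstack([params_to_vector(pt.params) for pt in self.points])

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, probabilities: np.ndarray,
                    model_kind: str, bounds=None) -> "DiscreteDistribution":
        probabilities = np.asarray(probabilities, dtype=float)
        total = probabilities.sum()
        if abs(total - 1.0) > 1e-12:  # keep exact values on a clean round-trip
            probabilities = probabilities / total
        pts = [SupportPoint(params_from_vector(model_kind, row), float(p))
               for row, p in zip(np.asarray(matrix, dtype=float), probabilities)]
        return cls(pts, model_kind, bounds)

    def reweighted(self, probabilities: np.ndarray) -> "DiscreteDistribution":
        """Same support, new probabilities (renormalized)."""
        probabilities = np.asarray(probabilities, dtype=float)
        if probabilities.shape != (len(self),):
            raise ValueError("probability vector length mismatch")
        total = probabilities.sum()
        if total <= 0:
            raise ValueError("probabilities sum to zero")
        return DiscreteDistribution(
            [SupportPoint(pt.params, float(p / total))
             for pt, p in zip(self.points, probabilities)],
            self.model_kind, self.bounds,
        )

    def summarize(self) -> pd.DataFrame:
        """Probability-weighted mean, median and SD per parameter."""
        w = self.probabilities()
        mat = self.params_matrix()
        means = w @ mat
        sds = np.sqrt(np.clip(w @ mat**2 - means**2, 0.0, None))
        medians = np.empty(mat.shape[1])
        for j in range(mat.shape[1]):
            order = np.argsort(mat[:, j])
            cum = np.cumsum(w[order])
            medians[j] = mat[order, j][np.searchsorted(cum, 0.5)]
        return pd.DataFrame(
            {"mean": means, "median": medians, "sd": sds},
            index=list(self.parameter_names),
        )


def default_bounds(means: Sequence[float]) -> np.ndarray:
    """Per-parameter [mean/100, mean*10] truncation bounds."""
    m = np.asarray(means, dtype=float)
    return np.column_stack([m / 100.0, m * 10.0])


def from_moments(means: Sequence[float], sds: Sequence[float], model_kind: str,
                 n_points: int = 1000, seed: int | None = None,
                 bounds: np.ndarray | None = None,
                 mean_tol: float = 0.02, max_adjust: int = 50) -> DiscreteDistribution:
    """Equal-weight support points matching published marginal moments.

    Each parameter is drawn independently from a log-normal whose
    arithmetic mean and SD match the inputs, truncated to ``bounds``
    (default [mean/100, mean*10]).  Truncation biases the realized mean,
    so columns are multiplicatively rescaled (and re-clipped) until every
    realized probability-weighted mean is within ``mean_tol`` of its
    target.  A zero SD collapses that parameter to its mean.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if np.any(means <= 0) or np.any(sds < 0):
        raise ValueError("means must be positive and sds non-negative")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if bounds is None:
        bounds = default_bounds(means)
    bounds = np.asarray(bounds, dtype=float)
    if np.any(bounds[:, 0] >= bounds[:, 1]):
        raise ValueError("infeasible bounds: lo >= hi")
    if np.any(means < bounds[:, 0]) or np.any(means > bounds[:, 1]):
        raise ValueError("infeasible bounds: target mean outside bounds")

    rng = np.random.default_rng(seed)
    d = means.size
    mat = np.empty((n_points, d))
    for j in range(d):
        if sds[j] == 0:
            mat[:, j] = means[j]
            continue
        cv2 = (sds[j] / means[j]) ** 2
        sigma2 = np.log1p(cv2)
        mu = np.log(means[j]) - sigma2 / 2.0
        col = rng.lognormal(mu, np.sqrt(sigma2), size=n_points)
        col = np.clip(col, bounds[j, 0], bounds[j, 1])
        for _ in range(max_adjust):
            realized = col.mean()
            if abs(realized - means[j]) <= mean_tol * means[j]:
                break
            col = np.clip(col * (means[j] / realized), bounds[j, 0], bounds[j, 1])
        else:
            raise ValueError(
                f"could not match mean of parameter {j} within {mean_tol:.0%} "
                f"under the given bounds"
            )
        mat[:, j] = col
    probs = np.full(n_points, 1.0 / n_points)
    return DiscreteDistribution.from_matrix(mat, probs, model_kind, bounds)


def summarize(dist: DiscreteDistribution) -> pd.DataFrame:
    """Weighted mean / median / SD per parameter (see the method)."""
    return dist.summarize()


# ---------------------------------------------------------------------------
# Density file round-trip (CSV: parameter columns + "prob")
# ---------------------------------------------------------------------------

def write_density(dist: DiscreteDistribution, path) -> None:
    df = pd.DataFrame(dist.params_matrix(), columns=list(dist.parameter_names))
    df["prob"] = dist.probabilities()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# mmdose density v1 model_kind={dist.model_kind}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_density(path) -> DiscreteDistribution:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("# mmdose density"):
            raise DensityFormatError(f"{path}: missing density header line")
        try:
            model_kind = header.strip().split("model_kind=")[1]
        except IndexError:
            raise DensityFormatError(f"{path}: header lacks model_kind") from None
        body = fh.read()
    if not body.strip():
        raise DensityFormatError(f"{path}: no support points")
    df = pd.read_csv(io.StringIO(body), float_precision="round_trip")
    if "prob" not in df.columns:
        raise DensityFormatError(f"{path}: missing 'prob' column")
    expected = list(param_names(model_kind))
    if list(df.columns[:-1]) != expected:
        raise DensityFormatError(
            f"{path}: columns {list(df.columns[:-1])} do not match {expected}"
        )
    probs = df["prob"].to_numpy(dtype=float)
    if np.any(probs < 0):
        bad = int(np.argmin(probs))
        raise DensityFormatError(f"{path}: negative probability at row {bad + 1}")
    total = probs.sum()
    if abs(total - 1.0) > 1e-6:
        raise DensityFormatError(f"{path}: probabilities sum to {total:.6g}, not 1")
    return DiscreteDistribution.from_matrix(
        df[expected].to_numpy(dtype=float), probs, model_kind
    )
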