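"""Observation-noise model for measured drug concentrations.

Assay imprecision is a polynomial in concentration,
``SD(C) = c0 + c1*C + c2*C^2 + c3*C^3`` (mg/L), estimated from replicate
assay data.  A multiplicative scalar ``gamma`` inflates the variance to
absorb process noise beyond the assay itself (mistimed samples or doses).
Each observation's weight in fitting is its Fisher information, the
inverse of its variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reference import ASSAY_SD_COEFFS


@dataclass(frozen=True)
class AssayErrorModel:
    c0: float = ASSAY_SD_COEFFS[0]
    c1: float = ASSAY_SD_COEFFS[1]
    c2: float = ASSAY_SD_COEFFS[2]
    c3: float = ASSAY_SD_COEFFS[3]
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.sd_at(0.0) <= 0:
            raise ValueError("sd at zero concentration must be positive")

    def with_gamma(self, gamma: float) -> "AssayErrorModel":
        return AssayErrorModel(self.c0, self.c1, self.c2, self.c3, gamma)

    def sd_at(self, c):
        """Assay SD (mg/L) at concentration c (mg/L); c must be >= 0."""
        c = np.asarray(c, dtype=float)
        if np.any(c < 0):
            raise ValueError("concentration must be non-negative")
        sd = self.c0 + self.c1 * c + self.c2 * c**2 + self.c3 * c**3
        if np.any(sd <= 0):
            raise ValueError("sd polynomial nonpositive in the requested range")
        return sd if sd.ndim else float(sd)

    def obs_variance(self, c):
        """Observation variance gamma * SD(c)^2 (mg^2/L^2)."""
        sd = np.asarray(self.sd_at(c))
        v = self.gamma * sd**2
        return v if v.ndim else float(v)

    def weight_at(self, c):
        """Fisher-information weight, 1 / variance (L^2/mg^2)."""
        v = np.asarray(self.obs_variance(c))
        w = 1.0 / v
        return w if w.ndim else float(w)
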