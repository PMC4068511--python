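"""Reference constants for piperacillin dosing in critically ill adults.

These are the published population summaries the package ships with: the
HPLC assay-error polynomial, the parameter summary of the covariate-linear
population PK model (nonrenal clearance ``cl_i``, renal clearance slope
``cl_s``, covariate-independent central volume ``v_i``, per-kg central
volume ``v_s``, and the intercompartmental rate constants), the
resistance-suppression trough targets for *Pseudomonas aeruginosa* (MIC
4 mg/L), and the covariate ranges of the pooled critically ill cohort.
"""

from __future__ import annotations

# Assay SD polynomial: SD(C) = 1.04 + 0.14*C  (mg/L), cubic terms zero.
ASSAY_SD_COEFFS: tuple[float, float, float, float] = (1.04, 0.14, 0.0, 0.0)

# Covariate-linear model population summary: arithmetic mean, median, SD.
# Units: cl_i L/h; cl_s L/h per (mL/min); v_i L; v_s L/kg; kcp, kpc 1/h.
POPULATION_MEANS = {
    "cl_i": 3.83, "cl_s": 0.11, "v_i": 4.54, "v_s": 0.12,
    "kcp": 6.74, "kpc": 9.14,
}
POPULATION_MEDIANS = {
    "cl_i": 2.79, "cl_s": 0.10, "v_i": 1.83, "v_s": 0.06,
    "kcp": 0.85, "kpc": 1.65,
}
POPULATION_SDS = {
    "cl_i": 3.35, "cl_s": 0.07, "v_i": 4.43, "v_s": 0.12,
    "kcp": 11.38, "kpc": 13.13,
}

# Steady-state trough targets (total plasma piperacillin, mg/L) suppressing
# emergence of resistance in a P. aeruginosa hollow-fiber model, MIC 4 mg/L.
TROUGH_TARGET_INTERMITTENT = 13.6  # q8h, 30-min infusions
TROUGH_TARGET_EXTENDED = 41.6      # q8h, 4-h infusions

# Pooled cohort covariate summaries: (low, high) range and median.
CRCL_RANGE_ML_MIN = (14.0, 245.7)
CRCL_MEDIAN_ML_MIN = 81.0
WEIGHT_RANGE_KG = (38.1, 122.5)
WEIGHT_MEDIAN_KG = 69.0
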