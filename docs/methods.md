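# Methods

## Problem and model

`mmdose` individualizes piperacillin dosing for critically ill patients
from sparse therapeutic drug monitoring (TDM) data. Drug disposition is a
two-compartment model driven by zero-order infusions: amounts `x1`
(central) and `x2` (peripheral), observed concentration `C = x1/vc`. Four
elimination variants are provided — first-order (`cl`), Michaelis-Menten
(`vmax`, `km` acting on concentration, so the elimination rate is
`vmax*C/(km + C)` in mg/h), parallel first-order plus saturable, and the
covariate-linear form used clinically, where

    cl = cl_i + cl_s * CrCL        (L/h; CrCL in mL/min)
    vc = v_i + v_s * weight        (L; weight in kg)

The covariate map is additive-linear. The published model legend names
the components (nonrenal clearance, renal slope, weight-proportional
volume) without writing the combining equation; the linear combination is
the conventional reading in nonparametric population PK practice, and the
slope `cl_s` is treated as L/h per mL/min (the legend's plain "L/h" is
dimensionally incomplete). No normalization of CrCL or weight is applied.
"Bolus" administrations are modeled as short zero-order infusions of
their stated duration; true instantaneous boluses are not supported.

## Numerics

Linear kinds are solved segment-by-segment in closed form: within each
interval of constant total infusion rate the 2x2 system has
`x(t) = Phi(t) x0 + Psi(t) b` with `Phi` the matrix exponential in Putzer
form and `Psi` its integral, written so that the no-elimination limit
(`cl -> 0`) stays finite. The two eigenvalues are provably real and
distinct whenever `kcp, kpc > 0`; a 1e-24 floor on the discriminant
guards the degenerate corner. Saturable kinds integrate with LSODA at
rtol 1e-8, atol 1e-10 mg, restarting at every infusion start/stop so the
input discontinuities are never smeared. Concentrations at an
infusion-start instant are left limits. Steady-state troughs solve the
one-interval affine fixed point exactly for linear kinds and iterate dose
by dose (0.1% successive-trough tolerance, 500-dose cap) otherwise.

## Observation noise

Assay SD is polynomial in concentration, `SD(C) = 1.04 + 0.14 C` mg/L by
default, with variance inflated by a scalar `gamma` (default 1; it can be
profiled over a user-supplied grid during population fitting, standing in
for the adaptive scalar of the reference implementation). Fitting weights
are Fisher information, `1/(gamma*SD^2)`. Likelihood variances use the
*predicted* concentration in the SD polynomial (an observed-based switch
exists for sensitivity checks); the synthetic generator deliberately uses
the *true* concentration on the simulation side — the asymmetry mirrors
how the error model is used in estimation versus how data arise.

## Population estimation (NPML)

The population distribution is estimated nonparametrically as a discrete
mixing distribution. Candidates are a scrambled-Sobol grid, log-uniform
within per-parameter bounds; weights are driven to the NPML optimum by
the multiplicative EM update

    w_j <- (1/N) sum_i L_ij w_j / sum_k L_ik w_k,

which is monotone in the marginal log likelihood, and — the weight
problem being concave — converges to the same optimum as the
interior-point solvers used by production NPAG implementations, only more
slowly. "Adaptive grid" refinement is approximated by perturbing
surviving points (probability > 1e-6) by ±20% per axis, re-solving, and
keeping the better solution, so refinement can never lower the
likelihood. Convergence tolerance is ΔLL 1e-4 with a 1000-cycle cap;
final points below weight 1e-9 are pruned. Likelihood rows are computed
in log space and shifted before exponentiation only when the row maximum
would underflow, so well-scaled problems see actual densities.

AIC is reported as `2k − 2LL` with `k` the structural parameter count;
likelihood-ratio p-values are only produced for nested kind pairs
(linear ⊂ parallel, Michaelis-Menten ⊂ parallel, linear ⊂
covariate-linear).

## Bayesian step and dose selection

A patient's posterior reweights the fixed support points by the normal
likelihood of their observed concentrations (log-space; empty data
returns the prior unchanged). Dose selection minimizes the
posterior-expected weighted squared error between predicted and target
concentrations. All planned future infusions share one amount — matching
the block-adjustment workflow this emulates — with times and durations
fixed by the user. For linear kinds the prediction is affine in dose, so
the objective is an exactly solvable quadratic; saturable kinds use
bounded Brent search with absolute tolerance equal to the template's
dose-grid step (10 mg default). Target weights default to assay
information `1/(gamma*SD(T)^2)`, the same convention as the fitting
stage, and can be overridden per target. Default dose bounds are
100–20000 mg; an out-of-bounds optimum is clipped and flagged rather
than silently accepted, and the exact optimum is reported alongside a
10 mg-rounded practical dose. Running the optimizer with *observed*
concentrations as targets inverts the problem and estimates the dose
that produced them; this is the validation statistic used throughout.

## Prior reconstruction from published summaries

When only marginal means and SDs of the population parameters are
available, `from_moments` builds an equal-weight prior from independent
truncated log-normal marginals (log-normality respects positivity and
the strong mean/median skew of the published summary). Truncation bounds
default to [mean/100, mean*10]; because truncation biases the realized
mean, each column is multiplicatively rescaled and re-clipped until its
weighted mean is within 2% of target. Correlations between parameters
are not reproducible from marginal summaries and are an explicit
limitation of the reconstructed prior.

## Synthetic cohorts

Virtual patients emulate the pooled critically ill cohorts behind the
reference model: covariates uniform over CrCL 14.0–245.7 mL/min and
weight 38.1–122.5 kg (only ranges and medians are published, hence the
uniform choice), truth sampled from the discrete prior by its
probabilities, observations at the canonical TDM designs (6 h; 0.5, 6 h;
0.5, 3, 6 h; 0.5, 1, 2, 3, 4, 6 h after the first dose) with normal
assay noise floored at 0.01 mg/L (an assay lower-limit stand-in). The
generator draws static parameters per patient; it does not emulate
intra-patient PK change over time, delayed-onset covariate drift, or
correlated parameters — so passing the in-silico loops shows internal
consistency of estimation and control under the model's own assumptions,
not robustness to the pathophysiological instability real ICU patients
show.

## Problem sizes and checks

The validation suites run at desk scale chosen by the package: the
two-point-mixture recovery uses 50 subjects × 3 observations and a
256-point starting grid; the dose-recovery loop uses 8 virtual patients,
a 1000-point reconstructed prior, two day-1 TDM samples and noisy day-2
concentrations as inversion targets against a 4000 mg reference; the
trough-attainment check optimizes a 20-dose q8h horizon and verifies the
recommended dose's steady-state trough against the 13.6 mg/L (30-min)
and 41.6 mg/L (4-h) resistance-suppression targets. Wide dose bounds are
used there because a median-parameter patient (effective cl ≈ 10.9 L/h,
vc ≈ 6.0 L, terminal half-life well under an hour) needs doses far above
the licensed range to hold those troughs at q8h — consistent with the
observation that markedly higher dosages can be required for trough
control. Independent oracles back every numerical path: segment-wise
RK45 for the closed form, hand-computed Bayes rule for the posterior,
brute-force double loops and dose-grid sweeps for the objective and
optimizer, and closed-form OLS for the regression statistics.

## Known limitations

Independent marginals in the reconstructed prior; EM convergence is slow
near degenerate optima (cycle counts in the thousands are normal);
axis-wise ±20% perturbation explores less than a true adaptive-grid
expansion; infusion durations and intervals are never optimized, only
the shared amount; targets are total concentrations (a fraction-unbound
multiplier is available for the fT>MIC utility only).
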