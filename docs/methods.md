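# Methods

## Structural model

Palbociclib concentrations follow a two-compartment disposition model with
first-order oral absorption and an absorption lag. With micro-constants
k10 = CL/V1, k12 = Q/V1, k21 = Q/V2 and macro-rates α, β (the roots of
s² − (k10+k12+k21)s + k10·k21), the single-dose solution is the standard
tri-exponential

  C(t) = (F·D·ka/V1)·[A·e^(−αt') + B·e^(−βt') + C·e^(−ka·t')],  t' = t − t_dose − t_lag,

zero before the lag has elapsed. Multi-dose profiles are exact linear
superpositions over the dose history. Units: doses mg, volumes l,
clearances l/h, concentrations ng/ml; because 1 mg/l = 1000 µg/l ≡
1000 ng/ml, a single factor of 1000 converts amount/volume to
concentration units (`MG_PER_L_TO_NG_PER_ML`, applied once).

When ka collides with α or β the coefficients are 0/0; instead of a
separate limiting branch, ka is perturbed by 1e-8 relative — far below
every other error source and verified finite in tests.

Body weight enters by fixed allometric scaling with exponents 0.75 (CL, Q)
and 1 (V1, V2) around a 70 kg reference — the reference weight is the
conventional allometric anchor, not an estimate.

Exposure metrics: AUC_0–τ = 1000·F·dose/CL (ng·h/ml; τ = 24 h on dosing
days at steady state, verified against numerical integration of the
profile to within 0.5%), and C_min as the model prediction immediately
before the day-15 dose of a cycle (24 h after the day-14 dose), the choice
that matches the day-15 sampling design. Dosing follows 21 days on / 7
days off in 28-day cycles, time origin at the first dose of cycle 1.

## Parameters and defaults

| parameter | unit | default | provenance |
|---|---|---|---|
| CL | l/h | 62.6 | reported population estimate |
| V1 | l | 2370 | reported population estimate |
| V2 | l | 682 | reported population estimate |
| Q | l/h | 48 | placeholder (supplement not available) |
| ka | 1/h | 0.5 | placeholder |
| t_lag | h | 1 | placeholder |
| F_rel (tablet) | – | 1 | assumed; tested as a covariate |
| ω² (CL, V1) | – | 0.09 each | assumed 30% CV, diagonal |
| σ_prop | – | 0.2 | assumed 20% proportional error |
| σ_add | ng/ml | 0 | off by default |
| reference weight | kg | 70 | convention |
| LLOQ | ng/ml | 1 | assay value not printed; configurable |

Placeholders are exactly that: configuration values on a plausible scale
for palbociclib, clearly not literature estimates, and overridable from
the YAML config (whose template carries a provenance comment per entry).

## Estimation

Random effects are log-normal on CL and V1 by default (diagonal Ω,
configurable). The individual (MAP) objective is

  g(η) = Σ_j [(y_j − f_j(η))²/σ²_j + log σ²_j] + ηᵀΩ⁻¹η,  σ²_j = (σ_prop f_j)² + σ²_add,

with BLQ observations excluded from the likelihood (M1 method; they count
only toward the one-sample-above-LLOQ inclusion rule). A subject with no
usable observations has mode η = 0 and contributes nothing to the marginal
OFV. The subject marginal is the Laplace approximation with interaction at
the η mode:

  OFV_i = g(η̂) + n_i·log 2π + log det Ω + log det(½∇²g(η̂)),

exact when g is quadratic in η. The population OFV is the sum over
subjects plus the frequentist-prior penalty
(θ−θ_prior)ᵀΣ_prior⁻¹(θ−θ_prior) on the natural scale of the
prior-weighted fixed effects; parameters flagged "no prior weight" (the
formulation effect, by construction) contribute nothing. The exact prior
means and uncertainties of the published prior model are not printed in
the available text, so priors are pure configuration; the default is a
weakly informative prior centred on the configured population values with
25% relative SD.

Numerics: the inner η problem is solved by damped Newton with central
finite differences (h = 1e-4), step length capped at 2 on the log scale
(larger steps are meaningless and can overflow the model when local
curvature is negative), backtracking line search, and — if it fails to
converge — a deterministic multistart from a fixed spread of η values.
The mode Hessian from the last Newton iteration is reused by the Laplace
term; non-positive-definite mode Hessians are eigenvalue-floored at 1e-10.
A variance floor of 1e-12 guards σ²_j at a zero prediction under purely
proportional error. The outer problem optimises log-transformed free
parameters (structural θ subset, Ω diagonal, σ) with L-BFGS-B, warm-
starting every subject's η across objective evaluations; relative OFV
tolerance 1e-6. On non-convergence the fit restarts from perturbed
initials (log-scale SD 0.15, fixed seed), up to 5 attempts in total, and
reports `converged=False` if none succeeds — the common converged path
costs one start. The covariance of the estimates is the inverse numerical
Hessian of OFV/2 at the optimum; because parameters are log-transformed,
the RSE (%) of an estimate is 100·SD(log estimate). An indefinite Hessian
falls back to a pseudo-inverse with a warning — itself a useful
ill-conditioning signal: on 1–2-sample-per-patient data the unpenalized
fit shows fixed-effect RSEs of 100%+ where the prior-penalized fit stays
below 31%, which is the entire case for the prior approach.

Laplace accuracy (measured against a mode-centred, width-scaled adaptive
quadrature oracle on one-η subjects): ~0.02–0.03 OFV units on 2-sample
subjects at 20% proportional error, below 0.01 on densely sampled
(16-point) subjects, shrinking further with more data or smaller residual
error. This is the intrinsic skewness of the integrand, not a defect; the
implementation agrees with an independently refined Laplace computation to
1e-6.

Covariate testing uses the OFV likelihood-ratio rule: a drop of ≥ 3.84
(χ²₁ at P < 0.05) for one extra parameter. The tablet/capsule effect is a
bioavailability multiplier estimated without prior weight.

## Exposure derivation rules

Per cycle, C_min and AUC_0–τ come from the empirical-Bayes parameters and
that cycle's daily dose; a cycle contributes only if the patient has a
usable sample in it. Patients need at least one sample above the LLOQ.
Response analyses average the available cycles (a single cycle is used
as-is). Toxicity and dose-reduction analyses must not let a cycle-2 dose
reduction contaminate exposure: such patients contribute cycle-1 values
only, and are excluded (not errored) if cycle 1 has no PK data. Quartiles
are linear-interpolation sample quantiles; a value exactly on a boundary
joins the upper group. Printed quartile boundaries from the original
cohort are data-dependent and not reproducible; the definition here is
fixed and documented instead.

## Outcome statistics

* Cochran–Armitage chi-square test for trend in proportions, equally
  spaced scores 1–4, no continuity correction, 1 df, two-sided — the
  construction of R's `prop.trend.test`, against which it is frozen in
  tests. Equally spaced scores reproduce the published quartile p-values;
  exposure-quartile medians as scores do not, and were rejected for that
  reason. The statistic is invariant to affine score changes.
* Univariable Cox proportional hazards via lifelines (Efron ties), HR
  reported per 10 ng/ml (C_min) or 100 ng·h/ml (AUC); Wald CIs at 90% to
  match the reported intervals; no multiplicity adjustment (none was
  applied in the source analysis).
* Median and first-quartile dichotomizations re-use the Cox machinery on
  the binary indicator (≥ cut = 1, consistent with the quartile tie rule).
* Kaplan–Meier product-limit curves; RMST as the exact area under the KM
  step function to a horizon τ (≤ each group's follow-up), difference with
  a large-sample normal CI.
* One published cell is knowingly non-reproducing: the all-AE/C_min row's
  printed p of 0.88 computes to ≈ 0.82 from its own printed counts (and
  its denominators are internally inconsistent); it is documented and
  excluded rather than "fixed".

## Synthetic cohorts

The generator emulates the PK substudy design with full ground truth:
log-normal weights (median 73 kg, log-SD 0.19 → IQR ≈ 65–84 kg); 125 mg
daily on days 1–21 of 28-day cycles; one sample per cycle on day 15 ± 5
(integer day offset, uniform) at a uniform 1–24 h after that day's dose
("random time points"); proportional residual error with BLQ flagging
below the LLOQ; ~8% of cycles missing a sample. Dose reductions are
logistic in true cycle-1 C_min with a positive default slope (intercept at
42% at 60 ng/ml, ≈ 0.22 log-odds per 10 ng/ml), and a cycle-2 reduction
(100 mg, occasionally 75 mg in the published 26:4 ratio) occurs in ~21% of
ever-reducers — marginals of roughly 42% ever and 9% in cycle 2. PFS is
exponential with a configurable log-linear C_min effect (default 0, the
null finding) and independent exponential censoring (median 730 days
against a 550-day baseline PFS); grade 3–4 AE indicators are logistic in
exposure with zero default slopes and intercepts at the observed marginal
rates (56% any, 45% neutropenia). The truth table stores every latent
quantity, including exact per-cycle C_min/AUC, enabling end-to-end error
quantification of the EBE pipeline (true-vs-derived AUC correlation > 0.8
at the 2-sample design).

Not emulated: switching to another CDK4/6 inhibitor, informative dropout,
time-varying adherence, covariate effects beyond weight, or assay features
beyond simple LLOQ censoring. Passing tests therefore demonstrate
correctness of the machinery under the stated generative model, not
robustness to real-data pathologies.

## Diagnostics

Goodness of fit uses population predictions (η = 0), individual (EBE)
predictions, and IWRES = (obs − ipred)/sd(ipred); rows with non-positive
residual SD are flagged rather than dropped silently. Conditional weighted
residuals are deliberately omitted in favour of IWRES + PRED — simpler and
directly testable (IWRES on model-simulated data is approximately standard
normal). The pcVPC scales each observation by bin-median PRED over its own
PRED, with quantile-based bins on time after dose (default 6), and
compares observed 5th/50th/95th percentiles per bin against percentile
bands from simulated replicates of the same design (default 200; bands are
stable from ~100 up, and nsim = 1 degenerates to that replicate). The
exact published binning is unstated; quantile binning is this package's
choice. pcVPC output is bit-for-bit seed-reproducible.

## Validation experiment sizes

The recovery experiment simulates 300 subjects with 8 log-spaced samples
spanning the absorption phase and one steady-state dosing interval, then
refits from a perturbed start (×1.3/0.7/1.4/0.8 on CL/V1/V2/Q) under the
weak default prior; CL, V1 and V2 return within 10% of the generating
values (V2, identified only through the distribution kinetics, carries the
largest estimator variance, ~5% SD). Null calibration uses 2000 zero-
effect cohorts of n = 340 for the trend test (type-I error 5% ± 1.5%) and
1000 of them for Cox 90% CI coverage of HR = 1 (90% ± 3%). The end-to-end
pipeline run uses the packaged default configuration (n = 340, ≤ 2 samples
per patient).

## Known limitations

* The Laplace marginal is an approximation; its intrinsic error at the
  sparse design is ~0.02–0.03 OFV units per subject (quantified above).
* FOCE, SAEM and importance sampling are out of scope; so are saturable
  kinetics, food effects and drug–drug interactions.
* BLQ handling is M1 (exclusion); likelihood-based censoring (M3) is not
  implemented.
* T_max/C_max are deliberately not derived — unidentifiable from one or
  two random samples per patient because of shrinkage.
* Cohort-dependent published numbers (median C_min 60 ng/ml, median AUC
  1886 ng·h/ml, the HRs, the quartile boundaries) cannot be reproduced
  without the patient data; default simulations land on the same scale
  (median C_min ≈ 59 ng/ml, AUC ≈ 1830 ng·h/ml) but only as plausibility
  checks.
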