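# palbopk

Population pharmacokinetics of palbociclib from sparse sampling, and the
exposure–response / exposure–toxicity analysis built on top of it.

Palbociclib, a CDK4/6 inhibitor used in hormone-receptor-positive advanced
breast cancer, is dosed 125 mg once daily on days 1–21 of 28-day cycles and
reduced (to 100 mg, then 75 mg) after qualifying toxicity. In large
pragmatic trials only one or two blood samples per patient are available,
taken at random times around day 15 of cycles 1 and 2. That is far too
little to identify a realistic PK model on its own — but enough once the
likelihood is penalized toward a previously published model (the
"frequentist prior", NONMEM's `$PRIOR` technique). From the fitted
hierarchical model, each patient's empirical-Bayes parameters yield a trough
concentration (C_min, ng/ml) and a steady-state AUC over one dosing
interval (AUC_0–τ = F·dose/CL, ng·h/ml), which then enter survival and
toxicity statistics: univariable Cox regression of progression-free
survival on exposure (HR per 10 ng/ml or per 100 ng·h/ml, 90% CI),
median/Q1 dichotomizations with Kaplan–Meier and restricted-mean-survival-
time checks, and the Cochran–Armitage chi-square test for trend in
adverse-event and dose-reduction proportions across exposure quartiles.

The package is aimed at pharmacometricians and clinical-trial statisticians
who want this pipeline as tested, reusable code. Because the patient-level
data are not public, a first-class synthetic-cohort generator emulates the
study design (weights, dosing, sampling windows, LLOQ censoring, cycle-2
dose reductions, configurable exposure effects on outcomes) with full
ground truth, so every stage can be validated end to end.

## The model

Two-compartment disposition with first-order absorption and a lag time,
solved in closed form (tri-exponential). Body weight enters by fixed
allometric scaling, exponent 0.75 on CL and Q and 1 on V1 and V2, with a
70 kg reference. Between-subject variability is log-normal
(θ_i = θ_pop·(W/70)^k·e^η, η ~ N(0, Ω)); residual error is proportional
(optionally plus additive). The population objective is −2× the penalized
marginal log-likelihood: each subject's marginal is approximated by the
Laplace method (with interaction) at the empirical-Bayes η mode, and the
fixed effects carry a normal penalty (θ−θ_prior)ᵀΣ_prior⁻¹(θ−θ_prior)
built from published estimates and their relative standard errors.
Nested models are compared by the OFV drop, with ≥ 3.84 points (χ²₁,
P < 0.05) declared significant.

## Worked example

```python
import numpy as np
from palbopk import (CohortConfig, TrendTable, apply_allometry, auc_tau,
                     default_population_parameters, generate_cohort,
                     build_exposure_table, trend_test, cox_univariable)
from palbopk.exposure import exposure_frame

pop = default_population_parameters()          # CL 62.6 l/h, V1 2370 l, V2 682 l
ind = apply_allometry(pop, weight=73.0)
print(f"typical clearance at 73 kg: {ind.cl:.1f} l/h")
print(f"steady-state AUC_0-tau at 125 mg: {auc_tau(ind, 125.0):.0f} ng*h/ml")

# trend in dose-reduction rates across trough-concentration quartiles
table = TrendTable(events=(25, 39, 36, 44), totals=(83, 87, 85, 86))
out = trend_test(table)
print(f"dose-reduction trend across Cmin quartiles: "
      f"chi2={out['chi2']:.2f}, p={out['p']:.3f}")

# a synthetic cohort through the exposure pipeline
cohort = generate_cohort(CohortConfig(n_patients=150, seed=1))
records = build_exposure_table(cohort.subjects, pop)
inc = exposure_frame(records).query("included")
print(f"median model-derived Cmin: {inc.cmin_avg.median():.1f} ng/ml")
merged = cohort.outcomes.merge(inc, on="subject_id")
res = cox_univariable(merged, "cmin_avg", unit_scale=10.0, ci_level=0.90)
print(f"PFS hazard ratio per 10 ng/ml Cmin: {res.hr:.2f} "
      f"(90% CI {res.ci_low:.2f}-{res.ci_high:.2f}, p={res.p:.2f})")
```

Output:

```
typical clearance at 73 kg: 64.6 l/h
steady-state AUC_0-tau at 125 mg: 1935 ng*h/ml
dose-reduction trend across Cmin quartiles: chi2=6.31, p=0.012
median model-derived Cmin: 58.9 ng/ml
PFS hazard ratio per 10 ng/ml Cmin: 0.94 (90% CI 0.85-1.03, p=0.26)
```

The typical clearance is the 62.6 l/h population value scaled to 73 kg;
the AUC is the bioavailable daily dose over that clearance. The trend test
flags rising dose-reduction rates across exposure quartiles (p ≈ 0.01),
while the Cox model on this null-effect synthetic cohort finds no
exposure–PFS association, as configured.

## Command line

```bash
palbopk init-config --path palbopk.yaml   # commented default configuration
palbopk all --config palbopk.yaml --outdir run/
```

`all` chains `simulate → fit → ebe → exposure → analyze`; `vpc` adds
goodness-of-fit tables/plots and a prediction-corrected visual predictive
check. Every stage writes a manifest (config hash, seed, library versions)
for exact reproduction.

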