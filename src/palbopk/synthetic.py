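"""Synthetic cohort generator emulating a palbociclib PK substudy with
sparse sampling.

Generates cohorts with known ground truth so that the whole pipeline —
estimation, exposure derivation, exposure-response / exposure-toxicity
statistics — is testable end to end without patient data. The design it
emulates: ~344 patients on palbociclib 125 mg once daily, days 1-21 of
28-day cycles; one blood sample at a random time on day 15 +/- 5 of cycles
1 and 2; dose reductions to 100 or 75 mg possible from cycle 2; PFS with a
configurable (default zero) log-linear trough-concentration effect;
grade 3-4 AE and dose-reduction indicators from logistic models in true
exposure.

What it deliberately does not emulate: switching to another CDK4/6
inhibitor, second-line fulvestrant pharmacology, dropout other than
independent censoring, or assay-level features beyond simple LLOQ
censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .pkmodel import (
    CYCLE_LENGTH_DAYS,
    DOSING_DAYS_PER_CYCLE,
    ConcentrationObservation,
    DoseEvent,
    PopulationParameters,
    SubjectRecord,
    auc_tau,
    concentration_profile,
    cycle_day15_predose_time,
    individual_from_eta,
    predict_cmin,
)

__all__ = [
    "default_population_parameters",
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_rich_pk",
]


def default_population_parameters() -> PopulationParameters:
    """Default simulation truth.

    CL, V1, V2 are the values estimated for palbociclib in a large sparse
    sampling cohort (62.6 l/h, 2370 l, 682 l). The remaining parameters are
    configuration placeholders on a plausible scale for palbociclib, not
    literature estimates: ka = 0.5 1/h, tlag = 1 h, Q = 48 l/h, f_rel = 1,
    30% CV log-normal between-subject variability on CL and V1, 20%
    proportional residual error.
    """
    return PopulationParameters(
        cl_pop=62.6, v1_pop=2370.0, v2_pop=682.0, q_pop=48.0,
        ka=0.5, tlag=1.0, f_rel=1.0,
        omega=np.diag([0.09, 0.09]), omega_names=("cl", "v1"),
        sigma_prop=0.2, sigma_add=0.0, wt_ref=70.0,
    )


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


@dataclass
class CohortConfig:
    """Study-design and outcome-model settings for cohort generation.

    Weight is log-normal with median 73 kg and log-SD 0.19 (chosen so the
    IQR is about 65-84 kg). Exposure effects act on the true cycle-1 trough
    concentration centred at 60 ng/ml; AE and dose-reduction indicators are
    logistic in that exposure, and PFS is exponential with a log-linear
    exposure effect (default zero: no exposure-response relationship).
    Dose-reduction marginals are set so that roughly 42% of patients ever
    reduce and roughly 9% already reduce in cycle 2, with 100 mg the usual
    first step and 75 mg the occasional second.
    """

    n_patients: int = 344
    seed: int = 2017
    # body weight: log-normal
    weight_median_kg: float = 73.0
    weight_log_sd: float = 0.19
    # dosing
    dose_mg: float = 125.0
    reduced_dose_mg: float = 100.0
    second_reduced_dose_mg: float = 75.0
    p_second_reduction: float = 4.0 / 30.0  # 75 mg among cycle-2 reducers
    n_cycles: int = 2
    # sampling design: one sample on day 15 +/- 5 per cycle, 1-24 h post dose
    sample_day_jitter: int = 5
    sample_min_h_post_dose: float = 1.0
    sample_max_h_post_dose: float = 24.0
    p_missing_sample: float = 0.08  # a cycle with no usable sample drawn
    # population model truth
    pop: PopulationParameters = field(default_factory=default_population_parameters)
    lloq: float = 1.0  # ng/ml
    p_tablet: float = 0.08
    # outcomes
    exposure_ref_ngml: float = 60.0
    log_hr_pfs_per_ngml: float = 0.0
    baseline_median_pfs_days: float = 550.0
    censor_median_days: float = 730.0
    p_first_line: float = 235.0 / 344.0
    ae_any_logit_intercept: float = _logit(0.56)
    ae_any_logit_slope_per_ngml: float = 0.0
    ae_neutropenia_logit_intercept: float = _logit(0.45)
    ae_neutropenia_logit_slope_per_ngml: float = 0.0
    dose_reduction_logit_intercept: float = _logit(0.42)
    dose_reduction_logit_slope_per_ngml: float = 0.022
    p_c2_reduction_given_ever: float = 30.0 / 144.0

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")
        for name in ("p_missing_sample", "p_tablet", "p_first_line",
                     "p_second_reduction", "p_c2_reduction_given_ever"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.lloq < 0:
            raise ValueError("lloq must be >= 0")
        if not 1 <= self.n_cycles:
            raise ValueError("n_cycles must be >= 1")
        if self.sample_day_jitter > 5:
            raise ValueError("sample day jitter beyond 5 leaves the dosing window")


@dataclass
class SyntheticCohort:
    """A generated cohort: analysable data plus the generating truth."""

    subjects: List[SubjectRecord]
    outcomes: pd.DataFrame  # subject_id, line, pfs_time, pfs_event, AE/DR flags
    truth: pd.DataFrame  # per-subject latent parameters and exact exposures
    config: CohortConfig


def _dose_schedule(config: CohortConfig, cycle_doses: List[float]) -> List[DoseEvent]:
    """Daily doses on days 1-21 of each 28-day cycle (times in h)."""
    doses = []
    for c, amt in enumerate(cycle_doses):
        start_day = c * CYCLE_LENGTH_DAYS
        for day in range(DOSING_DAYS_PER_CYCLE):
            doses.append(DoseEvent(time=(start_day + day) * 24.0, amount=amt))
    return doses


def generate_cohort(config: Optional[CohortConfig] = None,
                    seed: Optional[int] = None) -> SyntheticCohort:
    """Generate one cohort; identical seeds give identical cohorts.

    Per patient: weight draw, log-normal random effects, dose history with a
    possible cycle-2 dose reduction, one concentration sample per cycle at a
    random time on day 15 +/- 5 (proportional/additive residual error, BLQ
    flag below the LLOQ), and outcome rows (PFS with exponential event and
    censoring times, grade 3-4 AE flags, dose-reduction flags). The truth
    table stores every latent quantity, including exact per-cycle trough and
    AUC values, enabling end-to-end error quantification.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pop = config.pop
    d = len(pop.omega_names)
    omega_chol = np.linalg.cholesky(pop.omega + 1e-15 * np.eye(d))

    subjects: List[SubjectRecord] = []
    outcome_rows = []
    truth_rows = []
    log2 = float(np.log(2.0))
    for i in range(config.n_patients):
        sid = f"S{i + 1:04d}"
        weight = config.weight_median_kg * float(np.exp(
            rng.normal(0.0, config.weight_log_sd)))
        eta = omega_chol @ rng.standard_normal(d)
        formulation = "tablet" if rng.random() < config.p_tablet else "capsule"
        ind = individual_from_eta(pop, weight, eta, formulation)

        # cycle-1 exposure at the standard dose drives toxicity/reduction
        cmin_c1 = predict_cmin(ind, _dose_schedule(
            config, [config.dose_mg] * max(config.n_cycles, 1)), 1)
        auc_c1 = auc_tau(ind, config.dose_mg)
        x = cmin_c1 - config.exposure_ref_ngml

        p_dr_ever = 1.0 / (1.0 + np.exp(-(config.dose_reduction_logit_intercept
                                          + config.dose_reduction_logit_slope_per_ngml * x)))
        dr_ever = rng.random() < p_dr_ever
        dr_c2 = bool(dr_ever and rng.random() < config.p_c2_reduction_given_ever)
        dose_c2 = config.dose_mg
        if dr_c2:
            dose_c2 = (config.second_reduced_dose_mg
                       if rng.random() < config.p_second_reduction
                       else config.reduced_dose_mg)
        cycle_doses = [config.dose_mg] + [dose_c2] * (config.n_cycles - 1)
        doses = _dose_schedule(config, cycle_doses)

        observations = []
        for cycle in range(1, config.n_cycles + 1):
            if rng.random() < config.p_missing_sample:
                continue
            day_offset = int(rng.integers(-config.sample_day_jitter,
                                          config.sample_day_jitter + 1))
            day_idx = 14 + day_offset  # 0-based day within cycle
            t_dose = ((cycle - 1) * CYCLE_LENGTH_DAYS + day_idx) * 24.0
            t_obs = t_dose + rng.uniform(config.sample_min_h_post_dose,
                                         config.sample_max_h_post_dose)
            f_true = float(concentration_profile(ind, doses, np.array([t_obs]))[0])
            y = f_true * (1.0 + pop.sigma_prop * rng.standard_normal()) \
                + pop.sigma_add * rng.standard_normal()
            blq = y < config.lloq
            observations.append(ConcentrationObservation(
                time=t_obs, value=max(y, 0.0), blq=bool(blq), cycle=cycle))

        subjects.append(SubjectRecord(
            subject_id=sid, weight=weight, doses=tuple(doses),
            observations=tuple(observations), formulation=formulation))

        cmin_c2 = predict_cmin(ind, doses, 2) if config.n_cycles >= 2 else np.nan
        auc_c2 = auc_tau(ind, dose_c2) if config.n_cycles >= 2 else np.nan

        hazard = (log2 / config.baseline_median_pfs_days) * float(np.exp(
            config.log_hr_pfs_per_ngml * x))
        t_event = rng.exponential(1.0 / hazard)
        t_censor = rng.exponential(config.censor_median_days / log2)
        pfs_time = min(t_event, t_censor)
        pfs_event = t_event <= t_censor

        p_ae = 1.0 / (1.0 + np.exp(-(config.ae_any_logit_intercept
                                     + config.ae_any_logit_slope_per_ngml * x)))
        p_neut = 1.0 / (1.0 + np.exp(-(config.ae_neutropenia_logit_intercept
                                       + config.ae_neutropenia_logit_slope_per_ngml * x)))
        ae_any = rng.random() < p_ae
        ae_neut = bool(ae_any and rng.random() < p_neut / max(p_ae, p_neut))
        line = "first" if rng.random() < config.p_first_line else "second"

        outcome_rows.append({
            "subject_id": sid, "line": line,
            "pfs_time": pfs_time, "pfs_event": bool(pfs_event),
            "ae_grade34_any": bool(ae_any),
            "ae_grade34_neutropenia": bool(ae_neut),
            "dose_reduction_ever": bool(dr_ever),
            "dose_reduced_c2": dr_c2,
        })
        truth_rows.append({
            "subject_id": sid, "weight": weight,
            **{f"eta_{n}": float(e) for n, e in zip(pop.omega_names, eta)},
            "cl": ind.cl, "v1": ind.v1, "v2": ind.v2, "q": ind.q, "f": ind.f,
            "formulation": formulation,
            "cmin_c1_true": cmin_c1, "cmin_c2_true": cmin_c2,
            "auc_c1_true": auc_c1, "auc_c2_true": auc_c2,
            "dose_c1_mg": config.dose_mg, "dose_c2_mg": dose_c2 if config.n_cycles >= 2 else np.nan,
            "dose_reduced_c2": dr_c2,
        })

    return SyntheticCohort(
        subjects=subjects,
        outcomes=pd.DataFrame(outcome_rows),
        truth=pd.DataFrame(truth_rows),
        config=config,
    )


def generate_rich_pk(config: Optional[CohortConfig] = None,
                     n_samples_per_subject: int = 8,
                     seed: Optional[int] = None) -> SyntheticCohort:
    """Densely sampled cohort for estimator validation.

    Same patient generation as :func:`generate_cohort`, but with scheduled
    samples spanning the absorption phase and one full steady-state dosing
    interval (0.5-24 h after the day-15 dose of cycle 1, log-spaced), no
    dose reductions and no missing samples.
    """
    if n_samples_per_subject < 4:
        raise ValueError("n_samples_per_subject must be >= 4")
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pop = config.pop
    d = len(pop.omega_names)
    omega_chol = np.linalg.cholesky(pop.omega + 1e-15 * np.eye(d))
    offsets = np.geomspace(0.5, 24.0, n_samples_per_subject)
    t_ref = cycle_day15_predose_time(1)  # the day-15 dose of cycle 1

    subjects: List[SubjectRecord] = []
    truth_rows = []
    doses = _dose_schedule(config, [config.dose_mg])
    for i in range(config.n_patients):
        sid = f"R{i + 1:04d}"
        weight = config.weight_median_kg * float(np.exp(
            rng.normal(0.0, config.weight_log_sd)))
        eta = omega_chol @ rng.standard_normal(d)
        formulation = "tablet" if rng.random() < config.p_tablet else "capsule"
        ind = individual_from_eta(pop, weight, eta, formulation)
        t_obs = t_ref + offsets
        f_true = concentration_profile(ind, doses, t_obs)
        y = f_true * (1.0 + pop.sigma_prop * rng.standard_normal(len(t_obs))) \
            + pop.sigma_add * rng.standard_normal(len(t_obs))
        observations = tuple(
            ConcentrationObservation(time=float(t), value=max(float(v), 0.0),
                                     blq=bool(v < config.lloq), cycle=1)
            for t, v in zip(t_obs, y)
        )
        subjects.append(SubjectRecord(
            subject_id=sid, weight=weight, doses=tuple(doses),
            observations=observations, formulation=formulation))
        truth_rows.append({
            "subject_id": sid, "weight": weight,
            **{f"eta_{n}": float(e) for n, e in zip(pop.omega_names, eta)},
            "cl": ind.cl, "v1": ind.v1, "v2": ind.v2, "q": ind.q, "f": ind.f,
            "formulation": formulation,
            "cmin_c1_true": predict_cmin(ind, doses, 1),
            "auc_c1_true": auc_tau(ind, config.dose_mg),
        })

    return SyntheticCohort(subjects=subjects, outcomes=pd.DataFrame(),
                           truth=pd.DataFrame(truth_rows), config=config)
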