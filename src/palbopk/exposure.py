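"""Per-patient exposure metrics and the study's averaging/inclusion rules.

From the fitted population model, each patient's empirical-Bayes parameters
give a per-cycle trough concentration (Cmin, ng/ml) and steady-state AUC
over one dosing interval (AUC_0-tau, ng*h/ml). The rules applied on top:

* a patient is included only if at least one sample is above the LLOQ;
* a cycle contributes values only if the patient has a usable sample in it;
* for response analyses, available cycles are averaged (single cycle used
  as-is);
* for toxicity and dose-reduction analyses, a patient whose dose was
  reduced in cycle 2 contributes cycle-1 values only — and is excluded if
  cycle 1 has no PK data;
* included patients are split into quartiles of Cmin and AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .estimation import estimate_individual
from .pkmodel import (
    CYCLE_LENGTH_DAYS,
    PopulationParameters,
    SubjectRecord,
    auc_tau,
    predict_cmin,
)

__all__ = [
    "ExposureRecord",
    "lloq_inclusion",
    "average_exposure",
    "quartile_split",
    "derive_subject_exposure",
    "build_exposure_table",
    "exposure_frame",
]

ENDPOINTS = ("response", "toxicity", "dose_reduction")


@dataclass
class ExposureRecord:
    """Per-cycle and averaged exposure for one patient.

    Cycle values are ``None`` when the patient has no usable PK sample in
    that cycle; averages are ``None`` unless the patient is included and has
    at least one cycle value. Quartile labels (1-4) are assigned cohort-wide
    and only for included patients.
    """

    subject_id: str
    cmin_c1: Optional[float] = None
    cmin_c2: Optional[float] = None
    auc_c1: Optional[float] = None
    auc_c2: Optional[float] = None
    cmin_avg: Optional[float] = None
    auc_avg: Optional[float] = None
    dose_reduced_c2: bool = False
    included: bool = False
    quartile_cmin: Optional[int] = None
    quartile_auc: Optional[int] = None


def lloq_inclusion(subject: SubjectRecord) -> bool:
    """True iff at least one sample is above the lower limit of quantification."""
    return any(not o.blq for o in subject.observations)


def _mean_available(c1: Optional[float], c2: Optional[float]) -> Optional[float]:
    vals = [v for v in (c1, c2) if v is not None]
    return float(np.mean(vals)) if vals else None


def average_exposure(record: ExposureRecord,
                     endpoint: str) -> Optional[Tuple[float, float]]:
    """Endpoint-specific (Cmin, AUC) for one patient, or ``None`` if excluded.

    Response analyses average the available cycles. Toxicity and
    dose-reduction analyses must not reflect a cycle-2 dose reduction, so
    such patients contribute cycle-1 values only; if cycle 1 has no PK data
    they are excluded for that endpoint (signalled by ``None``, not an
    error).
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}")
    if not record.included:
        raise ValueError("average_exposure requires an included patient")
    if endpoint in ("toxicity", "dose_reduction") and record.dose_reduced_c2:
        if record.cmin_c1 is None or record.auc_c1 is None:
            return None
        return record.cmin_c1, record.auc_c1
    cmin = _mean_available(record.cmin_c1, record.cmin_c2)
    auc = _mean_available(record.auc_c1, record.auc_c2)
    if cmin is None or auc is None:
        return None
    return cmin, auc


def quartile_split(values: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    """Quartile boundaries and 1-4 labels for a set of exposure values.

    Boundaries are linear-interpolation sample quantiles (the numpy
    default). Groups are half-open intervals [q_k, q_{k+1}): a value lying
    exactly on a boundary goes to the upper group.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("quartile_split needs at least 4 values")
    boundaries = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    labels = np.searchsorted(boundaries, values, side="right") + 1
    return boundaries, labels


def _cycle_of_dose_time(time_h: float) -> int:
    return int(time_h // (CYCLE_LENGTH_DAYS * 24.0)) + 1


def derive_subject_exposure(subject: SubjectRecord,
                            pop: PopulationParameters) -> ExposureRecord:
    """Empirical-Bayes exposure metrics for one patient.

    Cmin per cycle is the model-predicted trough before the day-15 dose;
    AUC_0-tau is the cycle's daily dose divided by the individual clearance.
    A cycle yields values only when the patient has a usable (non-BLQ)
    sample in it.
    """
    included = lloq_inclusion(subject)
    record = ExposureRecord(subject_id=subject.subject_id, included=included)
    dose_by_cycle: Dict[int, float] = {}
    for d in subject.doses:
        dose_by_cycle.setdefault(_cycle_of_dose_time(d.time), d.amount)
    if len(dose_by_cycle) >= 2:
        record.dose_reduced_c2 = dose_by_cycle[2] < dose_by_cycle[1]
    if not included:
        return record
    ind = estimate_individual(subject, pop)
    cycles_with_data = {o.cycle for o in subject.usable_observations}
    for cycle in sorted(cycles_with_data):
        if cycle not in dose_by_cycle:
            continue
        cmin = predict_cmin(ind, subject.doses, cycle)
        auc = auc_tau(ind, dose_by_cycle[cycle])
        if cycle == 1:
            record.cmin_c1, record.auc_c1 = cmin, auc
        elif cycle == 2:
            record.cmin_c2, record.auc_c2 = cmin, auc
    record.cmin_avg = _mean_available(record.cmin_c1, record.cmin_c2)
    record.auc_avg = _mean_available(record.auc_c1, record.auc_c2)
    if record.cmin_avg is None:
        # included by the LLOQ rule but no cycle usable for metrics
        record.included = False
    return record


def build_exposure_table(subjects: Sequence[SubjectRecord],
                         pop: PopulationParameters) -> List[ExposureRecord]:
    """Exposure records for a cohort, with cohort-wide quartile labels
    assigned on the response-endpoint averages of included patients."""
    records = [derive_subject_exposure(s, pop) for s in subjects]
    inc = [r for r in records if r.included]
    if len(inc) >= 4:
        _, labels_cmin = quartile_split([r.cmin_avg for r in inc])
        _, labels_auc = quartile_split([r.auc_avg for r in inc])
        for r, lc, la in zip(inc, labels_cmin, labels_auc):
            r.quartile_cmin = int(lc)
            r.quartile_auc = int(la)
    return records


def exposure_frame(records: Sequence[ExposureRecord]) -> pd.DataFrame:
    """Tidy per-patient exposure table (one row per patient)."""
    return pd.DataFrame([{
        "subject_id": r.subject_id,
        "cmin_c1": r.cmin_c1, "cmin_c2": r.cmin_c2,
        "auc_c1": r.auc_c1, "auc_c2": r.auc_c2,
        "cmin_avg": r.cmin_avg, "auc_avg": r.auc_avg,
        "dose_reduced_c2": r.dose_reduced_c2,
        "included": r.included,
        "quartile_cmin": r.quartile_cmin, "quartile_auc": r.quartile_auc,
    } for r in records])
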