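"""Readers, writers and configuration for the analysis pipeline.

The pharmacometric event-record dataset follows the NONMEM convention: one
row per dose (EVID=1, AMT in mg) or observation (EVID=0, DV in ng/ml),
with subject-constant body weight and formulation carried on every row.
Validation is strict and reports the offending line and column.

Pipeline configuration is a YAML document; every constant that is not a
study-design fact is marked in the template as "assumed" or
"placeholder-for-supplement" so its provenance travels with the config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimation import FitConfig, PriorSpecification
from .pkmodel import (
    ConcentrationObservation,
    DoseEvent,
    PopulationParameters,
    SubjectRecord,
)
from .synthetic import CohortConfig, default_population_parameters

__all__ = [
    "DatasetError",
    "ConfigError",
    "EVENT_COLUMNS",
    "subjects_to_frame",
    "frame_to_subjects",
    "write_dataset",
    "read_dataset",
    "write_outcomes",
    "read_outcomes",
    "PipelineConfig",
    "load_config",
    "config_to_dict",
    "default_config_yaml",
    "build_manifest",
]

EVENT_COLUMNS = ["ID", "TIME", "EVID", "AMT", "DV", "BLQ", "MDV", "WT",
                 "FORM", "CYCLE"]


class DatasetError(ValueError):
    """Malformed event-record dataset; message names line and column."""


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


def subjects_to_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Event-record DataFrame (NONMEM-style) from subject records."""
    rows = []
    for s in subjects:
        events: List[tuple] = [(d.time, 1, d) for d in s.doses]
        events += [(o.time, 0, o) for o in s.observations]
        events.sort(key=lambda e: (e[0], -e[1]))  # dose before obs at a tie
        for t, evid, ev in events:
            if evid == 1:
                rows.append({"ID": s.subject_id, "TIME": t, "EVID": 1,
                             "AMT": ev.amount, "DV": np.nan, "BLQ": 0, "MDV": 1,
                             "WT": s.weight, "FORM": s.formulation,
                             "CYCLE": int(t // (28 * 24)) + 1})
            else:
                rows.append({"ID": s.subject_id, "TIME": t, "EVID": 0,
                             "AMT": np.nan, "DV": ev.value, "BLQ": int(ev.blq),
                             "MDV": 0, "WT": s.weight, "FORM": s.formulation,
                             "CYCLE": ev.cycle})
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def _fail(line: int, column: str, msg: str) -> None:
    raise DatasetError(f"line {line}, column {column}: {msg}")


def frame_to_subjects(df: pd.DataFrame, first_line: int = 2) -> List[SubjectRecord]:
    """Validate an event-record frame and build subject records.

    ``first_line`` is the file line number of the first data row, used in
    error messages (2 for a CSV with a header).
    """
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"line 1, column {missing[0]}: missing required "
                           f"column(s) {missing}")
    subjects: List[SubjectRecord] = []
    for sid, grp in df.groupby("ID", sort=False):
        doses, observations = [], []
        weights = grp["WT"].unique()
        last_time = -np.inf
        for idx, row in grp.iterrows():
            line = int(idx) + first_line
            try:
                t = float(row["TIME"])
            except (TypeError, ValueError):
                _fail(line, "TIME", f"not a number: {row['TIME']!r}")
            if not np.isfinite(t) or t < 0:
                _fail(line, "TIME", f"must be a finite non-negative number, got {t}")
            if t < last_time:
                _fail(line, "TIME", f"times not sorted within subject {sid}")
            last_time = t
            evid = row["EVID"]
            if evid not in (0, 1):
                _fail(line, "EVID", f"must be 0 (observation) or 1 (dose), got {evid}")
            form = row["FORM"]
            if form not in ("capsule", "tablet"):
                _fail(line, "FORM", f"must be capsule or tablet, got {form!r}")
            wt = float(row["WT"])
            if not wt > 0:
                _fail(line, "WT", f"must be positive, got {wt}")
            if evid == 1:
                amt = row["AMT"]
                if pd.isna(amt) or not float(amt) > 0:
                    _fail(line, "AMT", "dose rows need a positive amount")
                doses.append(DoseEvent(time=t, amount=float(amt), formulation=form))
            else:
                blq = int(row["BLQ"]) if not pd.isna(row["BLQ"]) else 0
                if blq not in (0, 1):
                    _fail(line, "BLQ", f"must be 0 or 1, got {blq}")
                dv = row["DV"]
                if pd.isna(dv) and not blq:
                    _fail(line, "DV", "observation rows need DV or BLQ=1")
                cyc = row["CYCLE"]
                if pd.isna(cyc) or int(cyc) < 1:
                    _fail(line, "CYCLE", f"must be a positive integer, got {cyc}")
                observations.append(ConcentrationObservation(
                    time=t, value=0.0 if pd.isna(dv) else float(dv),
                    blq=bool(blq), cycle=int(cyc)))
        if len(weights) != 1:
            _fail(int(grp.index[0]) + first_line, "WT",
                  f"subject {sid} has non-constant weight {sorted(weights)}")
        subjects.append(SubjectRecord(
            subject_id=str(sid), weight=float(weights[0]), doses=tuple(doses),
            observations=tuple(observations),
            formulation=str(grp["FORM"].iloc[0])))
    return subjects


def write_dataset(subjects: Sequence[SubjectRecord], path: str | Path) -> None:
    # %.17g keeps the write -> read round trip lossless for doubles
    subjects_to_frame(subjects).to_csv(path, index=False, float_format="%.17g")


def read_dataset(path: str | Path) -> List[SubjectRecord]:
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"dataset file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    return frame_to_subjects(df)


_OUTCOME_COLUMNS = ["subject_id", "line", "pfs_time", "pfs_event",
                    "ae_grade34_any", "ae_grade34_neutropenia",
                    "dose_reduction_ever", "dose_reduced_c2"]


def write_outcomes(outcomes: pd.DataFrame, path: str | Path) -> None:
    outcomes.to_csv(path, index=False)


def read_outcomes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _OUTCOME_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"outcome table missing column(s) {missing}")
    for col in ("pfs_event", "ae_grade34_any", "ae_grade34_neutropenia",
                "dose_reduction_ever", "dose_reduced_c2"):
        df[col] = df[col].astype(bool)
    return df


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, resolved from YAML."""

    seed: int = 1
    pop: PopulationParameters = field(default_factory=default_population_parameters)
    prior: Optional[PriorSpecification] = None
    fit: FitConfig = field(default_factory=FitConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    lloq: float = 1.0
    ci_level: float = 0.90
    trend_scores: Tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    hr_unit_cmin: float = 10.0  # HR reported per 10 ng/ml Cmin
    hr_unit_auc: float = 100.0  # HR reported per 100 ng*h/ml AUC
    vpc_nsim: int = 200
    vpc_bins: int = 6
    raw: Dict = field(default_factory=dict)


def _require(mapping: Dict, key: str, context: str):
    if key not in mapping:
        raise ConfigError(f"missing config key '{key}' in section '{context}'")
    return mapping[key]


def _pop_from_dict(d: Dict) -> PopulationParameters:
    kwargs = dict(d)
    omega_diag = kwargs.pop("omega_diag", None)
    omega_names = tuple(kwargs.pop("omega_names", ("cl", "v1")))
    if omega_diag is not None:
        kwargs["omega"] = np.diag([float(v) for v in omega_diag])
        kwargs["omega_names"] = omega_names
    try:
        return PopulationParameters(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"bad population parameter section: {exc}") from exc


def default_prior_specification(pop: Optional[PopulationParameters] = None,
                                rse: float = 0.25) -> PriorSpecification:
    """Weakly informative prior centred on the model's own population values.

    The published prior model's exact means/uncertainties live in an
    unavailable supplement, so they enter this package purely as
    configuration; the default centres the prior on the configured
    population parameters with a 25% relative SD on each, and leaves the
    formulation effect (f_rel) without prior weight, mirroring how a
    covariate under test is handled.
    """
    pop = pop or default_population_parameters()
    means = {"cl_pop": pop.cl_pop, "v1_pop": pop.v1_pop, "v2_pop": pop.v2_pop,
             "q_pop": pop.q_pop, "ka": pop.ka, "tlag": pop.tlag,
             "f_rel": pop.f_rel}
    rses = {k: rse for k in means}
    return PriorSpecification.from_rse(means, rses, no_weight=("f_rel",))


def load_config(path: Optional[str | Path] = None) -> PipelineConfig:
    """Load and validate the pipeline YAML; ``None`` yields the defaults."""
    raw: Dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("top-level YAML must be a mapping")
    cfg = PipelineConfig(raw=raw)
    cfg.seed = int(raw.get("seed", cfg.seed))
    if "population" in raw:
        cfg.pop = _pop_from_dict(raw["population"])
    prior_raw = raw.get("prior", {"rse_default": 0.25})
    if prior_raw is not None:
        if "means" in prior_raw:
            means = {k: float(v) for k, v in _require(prior_raw, "means", "prior").items()}
            rses = {k: float(v) for k, v in _require(prior_raw, "rse", "prior").items()}
            cfg.prior = PriorSpecification.from_rse(
                means, rses, no_weight=tuple(prior_raw.get("no_weight", ())))
        else:
            cfg.prior = default_prior_specification(
                cfg.pop, rse=float(prior_raw.get("rse_default", 0.25)))
    if "fit" in raw:
        fit_raw = dict(raw["fit"])
        if "estimate_theta" in fit_raw:
            fit_raw["estimate_theta"] = tuple(fit_raw["estimate_theta"])
        try:
            cfg.fit = FitConfig(**fit_raw)
        except TypeError as exc:
            raise ConfigError(f"bad fit section: {exc}") from exc
    if "cohort" in raw:
        cohort_raw = dict(raw["cohort"])
        cohort_raw.setdefault("seed", cfg.seed)
        try:
            cfg.cohort = CohortConfig(pop=cfg.pop, **cohort_raw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad cohort section: {exc}") from exc
    else:
        cfg.cohort = CohortConfig(pop=cfg.pop, seed=cfg.seed)
    analysis = raw.get("analysis", {})
    cfg.lloq = float(raw.get("exposure", {}).get("lloq", cfg.cohort.lloq))
    cfg.ci_level = float(analysis.get("ci_level", 0.90))
    if not 0 < cfg.ci_level < 1:
        raise ConfigError(f"ci_level must be in (0, 1), got {cfg.ci_level}")
    cfg.trend_scores = tuple(float(s) for s in analysis.get("scores", (1, 2, 3, 4)))
    cfg.hr_unit_cmin = float(analysis.get("hr_unit_cmin", 10.0))
    cfg.hr_unit_auc = float(analysis.get("hr_unit_auc", 100.0))
    vpc = raw.get("vpc", {})
    cfg.vpc_nsim = int(vpc.get("nsim", 200))
    cfg.vpc_bins = int(vpc.get("bins", 6))
    return cfg


def config_to_dict(cfg: PipelineConfig) -> Dict:
    """JSON-serialisable snapshot of a resolved configuration."""
    pop = cfg.pop
    out: Dict = {
        "seed": cfg.seed,
        "population": {
            "cl_pop": pop.cl_pop, "v1_pop": pop.v1_pop, "v2_pop": pop.v2_pop,
            "q_pop": pop.q_pop, "ka": pop.ka, "tlag": pop.tlag,
            "f_rel": pop.f_rel, "omega_diag": np.diag(pop.omega).tolist(),
            "omega_names": list(pop.omega_names), "sigma_prop": pop.sigma_prop,
            "sigma_add": pop.sigma_add, "wt_ref": pop.wt_ref,
        },
        "fit": {"estimate_theta": list(cfg.fit.estimate_theta),
                "estimate_omega": cfg.fit.estimate_omega,
                "estimate_sigma_prop": cfg.fit.estimate_sigma_prop,
                "n_starts": cfg.fit.n_starts, "seed": cfg.fit.seed},
        "cohort": {"n_patients": cfg.cohort.n_patients,
                   "seed": cfg.cohort.seed, "lloq": cfg.cohort.lloq,
                   "dose_mg": cfg.cohort.dose_mg,
                   "n_cycles": cfg.cohort.n_cycles},
        "analysis": {"ci_level": cfg.ci_level,
                     "scores": list(cfg.trend_scores),
                     "hr_unit_cmin": cfg.hr_unit_cmin,
                     "hr_unit_auc": cfg.hr_unit_auc},
        "vpc": {"nsim": cfg.vpc_nsim, "bins": cfg.vpc_bins},
    }
    if cfg.prior is not None:
        out["prior"] = {
            "names": list(cfg.prior.names),
            "theta_prior": cfg.prior.theta_prior.tolist(),
            "theta_prior_sd": np.sqrt(np.diag(cfg.prior.theta_prior_cov)).tolist(),
            "weight_flags": cfg.prior.weight_flags.tolist(),
        }
    return out


DEFAULT_CONFIG_TEMPLATE = """\
# palbopk pipeline configuration
seed: 1

population:            # simulation truth / fit initials
  cl_pop: 62.6         # l/h   (published estimate)
  v1_pop: 2370.0       # l     (published estimate)
  v2_pop: 682.0        # l     (published estimate)
  q_pop: 48.0          # l/h   (placeholder-for-supplement)
  ka: 0.5              # 1/h   (placeholder-for-supplement)
  tlag: 1.0            # h     (placeholder-for-supplement)
  f_rel: 1.0           # tablet vs capsule bioavailability (assumed)
  omega_diag: [0.09, 0.09]   # log-scale variances (assumed, 30% CV)
  omega_names: [cl, v1]
  sigma_prop: 0.2      # proportional residual SD (assumed)
  sigma_add: 0.0       # ng/ml (assumed)
  wt_ref: 70.0         # kg, allometric reference (assumed, conventional)

prior:                 # frequentist prior on the fixed effects
  rse_default: 0.25    # relative SD of the prior around `population`

fit:
  estimate_theta: [cl_pop, v1_pop, v2_pop, q_pop]
  n_starts: 5

cohort:                # study design being emulated
  n_patients: 340
  # weight: log-normal, median 73 kg (study design); dosing 125 mg days 1-21 / 28
  # one sample on day 15 +/- 5 of cycles 1-2, 1-24 h post dose (study design)

exposure:
  lloq: 1.0            # ng/ml (assay LLOQ not printed; assumed)

analysis:
  ci_level: 0.90       # matches the published intervals
  scores: [1, 2, 3, 4] # trend-test scores
  hr_unit_cmin: 10.0   # HR per 10 ng/ml (published convention)
  hr_unit_auc: 100.0   # HR per 100 ng*h/ml (published convention)

vpc:
  nsim: 200
  bins: 6
"""


def default_config_yaml(path: str | Path) -> None:
    Path(path).write_text(DEFAULT_CONFIG_TEMPLATE)


def build_manifest(cfg: PipelineConfig, seed: int,
                   outputs: Sequence[str]) -> Dict:
    """Reproducibility manifest: config hash, seed and library versions."""
    import scipy

    snapshot = config_to_dict(cfg)
    digest = hashlib.sha256(
        json.dumps(snapshot, sort_keys=True).encode()).hexdigest()
    return {
        "package": "palbopk",
        "version": __version__,
        "config_sha256": digest,
        "config": snapshot,
        "seed": seed,
        "outputs": list(outputs),
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__},
    }
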