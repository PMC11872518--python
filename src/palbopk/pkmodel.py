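"""Structural PK model for palbociclib: two-compartment disposition with
first-order oral absorption and an absorption lag time.

Units convention (applied consistently across the package):

* doses in mg, volumes in l, clearances in l/h, times in h,
  concentrations in ng/ml.
* ``dose [mg] / volume [l]`` is mg/l; 1 mg/l = 1000 µg/l and
  1 µg/l = 1 ng/ml, so amounts are converted to concentration units with a
  single factor of 1000 (``MG_PER_L_TO_NG_PER_ML``), applied once in
  :func:`concentration_single_dose`.

Typical individual parameters are obtained from population values by fixed
allometric scaling of body weight (exponent 0.75 on clearances, 1 on
volumes); individual parameters add log-normal random effects on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Sequence, Tuple

import numpy as np

__all__ = [
    "MG_PER_L_TO_NG_PER_ML",
    "ALLOMETRIC_EXPONENTS",
    "PopulationParameters",
    "IndividualParameters",
    "DoseEvent",
    "ConcentrationObservation",
    "SubjectRecord",
    "apply_allometry",
    "individual_from_eta",
    "concentration_single_dose",
    "concentration_profile",
    "auc_tau",
    "predict_cmin",
    "CYCLE_LENGTH_DAYS",
    "DOSING_DAYS_PER_CYCLE",
]

#: mg/l -> ng/ml conversion; the only place mass units are converted.
MG_PER_L_TO_NG_PER_ML = 1000.0

#: Fixed allometric exponents: 0.75 for clearances (cl, q), 1 for volumes.
ALLOMETRIC_EXPONENTS: Dict[str, float] = {"cl": 0.75, "q": 0.75, "v1": 1.0, "v2": 1.0}

#: Dosing schedule constants: 28-day cycles, drug on days 1-21 (3 weeks on,
#: 1 week off).
CYCLE_LENGTH_DAYS = 28
DOSING_DAYS_PER_CYCLE = 21

#: Relative perturbation applied to ka when it collides with a disposition
#: macro-rate (alpha or beta), avoiding the 0/0 limit branch.
_KA_DEGENERACY_EPS = 1e-8


class InvalidInputError(ValueError):
    """Raised when a PK operation receives out-of-domain input."""


class MissingCycleError(InvalidInputError):
    """Raised when a dose history does not contain the requested cycle."""


@dataclass
class PopulationParameters:
    """Population (typical) parameters of the palbociclib PK model.

    Random effects are log-normal; ``omega`` is the covariance matrix of the
    log-scale random effects, one row/column per name in ``omega_names``.
    Residual error is proportional (``sigma_prop``, dimensionless CV) plus
    additive (``sigma_add``, ng/ml).
    """

    cl_pop: float  # clearance, l/h
    v1_pop: float  # central volume, l
    v2_pop: float  # peripheral volume, l
    q_pop: float  # inter-compartmental clearance, l/h
    ka: float  # absorption rate, 1/h
    tlag: float  # absorption lag, h
    f_rel: float = 1.0  # relative bioavailability of tablets vs capsules
    omega: np.ndarray = field(default_factory=lambda: 0.09 * np.eye(2))
    omega_names: Tuple[str, ...] = ("cl", "v1")
    sigma_prop: float = 0.2
    sigma_add: float = 0.0
    wt_ref: float = 70.0  # reference body weight, kg

    def __post_init__(self) -> None:
        self.omega = np.atleast_2d(np.asarray(self.omega, dtype=float))
        for name in ("cl_pop", "v1_pop", "v2_pop", "q_pop", "ka", "f_rel", "wt_ref"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be strictly positive")
        if self.tlag < 0:
            raise InvalidInputError("tlag must be non-negative")
        if self.sigma_prop < 0 or self.sigma_add < 0:
            raise InvalidInputError("residual error SDs must be non-negative")
        if self.sigma_prop == 0 and self.sigma_add == 0:
            raise InvalidInputError("at least one of sigma_prop, sigma_add must be > 0")
        k = len(self.omega_names)
        if self.omega.shape != (k, k):
            raise InvalidInputError(
                f"omega must be {k}x{k} to match omega_names {self.omega_names}"
            )
        if not np.allclose(self.omega, self.omega.T):
            raise InvalidInputError("omega must be symmetric")
        if np.any(np.linalg.eigvalsh(self.omega) < -1e-12):
            raise InvalidInputError("omega must be positive semidefinite")
        unknown = set(self.omega_names) - {"cl", "v1", "v2", "q", "ka", "f"}
        if unknown:
            raise InvalidInputError(f"unknown random-effect names: {sorted(unknown)}")


@dataclass
class IndividualParameters:
    """One subject's PK parameters after allometry and random effects."""

    cl: float  # l/h
    v1: float  # l
    v2: float  # l
    q: float  # l/h
    ka: float  # 1/h
    tlag: float  # h
    f: float = 1.0
    eta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    converged: bool = True  # set False when EBE optimisation failed

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=float)
        for name in ("cl", "v1", "v2", "q", "ka", "f"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be strictly positive")
        if self.tlag < 0:
            raise InvalidInputError("tlag must be non-negative")
        if not np.all(np.isfinite(self.eta)):
            raise InvalidInputError("eta must be finite")


@dataclass(frozen=True)
class DoseEvent:
    """An oral dose: time in hours since first dose, amount in mg."""

    time: float
    amount: float
    formulation: str = "capsule"

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise InvalidInputError("dose amount must be > 0")
        if self.time < 0:
            raise InvalidInputError("dose time must be >= 0")
        if self.formulation not in ("capsule", "tablet"):
            raise InvalidInputError("formulation must be 'capsule' or 'tablet'")


@dataclass(frozen=True)
class ConcentrationObservation:
    """A plasma concentration sample; ``blq`` marks censoring below the LLOQ."""

    time: float  # h since first dose
    value: float  # ng/ml (0 allowed when blq)
    blq: bool = False
    cycle: int = 1

    def __post_init__(self) -> None:
        if self.time < 0:
            raise InvalidInputError("observation time must be >= 0")
        if not self.blq and self.value < 0:
            raise InvalidInputError("non-BLQ observation value must be >= 0")
        if self.cycle < 1:
            raise InvalidInputError("cycle index is 1-based")


@dataclass
class SubjectRecord:
    """One patient's dosing history and concentration observations."""

    subject_id: str
    weight: float  # kg
    doses: Tuple[DoseEvent, ...] = ()
    observations: Tuple[ConcentrationObservation, ...] = ()
    formulation: str = "capsule"

    def __post_init__(self) -> None:
        self.doses = tuple(self.doses)
        self.observations = tuple(self.observations)
        if self.weight <= 0:
            raise InvalidInputError(f"subject {self.subject_id}: weight must be > 0")
        times = [d.time for d in self.doses]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise InvalidInputError(
                f"subject {self.subject_id}: doses must be sorted by time"
            )

    @property
    def usable_observations(self) -> Tuple[ConcentrationObservation, ...]:
        """Observations entering the likelihood (non-BLQ)."""
        return tuple(o for o in self.observations if not o.blq)


def apply_allometry(pop: PopulationParameters, weight: float) -> IndividualParameters:
    """Typical parameters for a subject of the given body weight.

    Clearances scale with (weight / wt_ref)^0.75 and volumes with
    (weight / wt_ref)^1; absorption parameters and bioavailability are
    weight-independent.
    """
    if weight <= 0:
        raise InvalidInputError("weight must be strictly positive")
    w = weight / pop.wt_ref
    return IndividualParameters(
        cl=pop.cl_pop * w ** ALLOMETRIC_EXPONENTS["cl"],
        v1=pop.v1_pop * w ** ALLOMETRIC_EXPONENTS["v1"],
        v2=pop.v2_pop * w ** ALLOMETRIC_EXPONENTS["v2"],
        q=pop.q_pop * w ** ALLOMETRIC_EXPONENTS["q"],
        ka=pop.ka,
        tlag=pop.tlag,
        f=1.0,
        eta=np.zeros(len(pop.omega_names)),
    )


def individual_from_eta(
    pop: PopulationParameters,
    weight: float,
    eta: Sequence[float],
    formulation: str = "capsule",
) -> IndividualParameters:
    """Individual parameters: allometry-scaled typical values times exp(eta).

    ``eta`` is aligned with ``pop.omega_names``. Tablet subjects get the
    ``f_rel`` bioavailability multiplier.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (len(pop.omega_names),):
        raise InvalidInputError(
            f"eta must have length {len(pop.omega_names)} (omega_names)"
        )
    typ = apply_allometry(pop, weight)
    values = {
        "cl": typ.cl, "v1": typ.v1, "v2": typ.v2, "q": typ.q,
        "ka": typ.ka, "f": pop.f_rel if formulation == "tablet" else 1.0,
    }
    for name, e in zip(pop.omega_names, eta):
        values[name] *= float(np.exp(e))
    return replace(
        typ, cl=values["cl"], v1=values["v1"], v2=values["v2"], q=values["q"],
        ka=values["ka"], f=values["f"], eta=eta,
    )


def _macro_rates(ind: IndividualParameters) -> Tuple[float, float]:
    """Disposition macro-rates (alpha, beta) from the micro-constants."""
    k10 = ind.cl / ind.v1
    k12 = ind.q / ind.v1
    k21 = ind.q / ind.v2
    s = k10 + k12 + k21
    disc = np.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    return alpha, beta


def _biexponential_coefficients(
    ind: IndividualParameters,
) -> Tuple[float, float, float, float, float, float]:
    """Return (alpha, beta, ka, A, B, C) of the unit-dose tri-exponential.

    ka collisions with alpha or beta are resolved by a documented relative
    perturbation of ka (1e-8) rather than a separate limiting formula.
    """
    alpha, beta = _macro_rates(ind)
    ka = ind.ka
    while abs(ka - alpha) < _KA_DEGENERACY_EPS * ka or abs(ka - beta) < _KA_DEGENERACY_EPS * ka:
        ka *= 1.0 + _KA_DEGENERACY_EPS
    k21 = ind.q / ind.v2
    coef_a = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    coef_b = (k21 - beta) / ((ka - beta) * (alpha - beta))
    coef_c = (k21 - ka) / ((alpha - ka) * (beta - ka))
    return alpha, beta, ka, coef_a, coef_b, coef_c


def concentration_single_dose(
    ind: IndividualParameters, dose: DoseEvent, t: float | np.ndarray
) -> float | np.ndarray:
    """Plasma concentration (ng/ml) at time ``t`` from a single oral dose.

    Closed-form tri-exponential solution of the two-compartment model with
    first-order absorption; zero before the absorption lag has elapsed.
    ``t`` is in hours since first dose (same clock as ``dose.time``).
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    tp = t - dose.time - ind.tlag  # time since absorption starts
    alpha, beta, ka, ca, cb, cc = _biexponential_coefficients(ind)
    scale = MG_PER_L_TO_NG_PER_ML * ind.f * dose.amount * ka / ind.v1
    tp_pos = np.where(tp > 0, tp, 0.0)
    conc = scale * (
        ca * np.exp(-alpha * tp_pos)
        + cb * np.exp(-beta * tp_pos)
        + cc * np.exp(-ka * tp_pos)
    )
    conc = np.where(tp > 0, conc, 0.0)
    return float(conc) if scalar else conc


def concentration_profile(
    ind: IndividualParameters,
    doses: Sequence[DoseEvent],
    times: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Concentrations at ``times`` from a dose history, by linear superposition.

    ``doses`` must be sorted by time; an empty history yields zeros.
    """
    times = np.asarray(times, dtype=float)
    out_shape = times.shape
    times = np.atleast_1d(times)
    if not doses:
        return np.zeros(out_shape)
    dose_times = np.array([d.time for d in doses])
    if np.any(np.diff(dose_times) < 0):
        raise InvalidInputError("doses must be sorted by time")
    amounts = np.array([d.amount for d in doses])
    alpha, beta, ka, ca, cb, cc = _biexponential_coefficients(ind)
    scale = MG_PER_L_TO_NG_PER_ML * ind.f * ka / ind.v1
    tp = times[:, None] - dose_times[None, :] - ind.tlag  # (n_times, n_doses)
    active = tp > 0
    tp_pos = np.where(active, tp, 0.0)
    contrib = (
        ca * np.exp(-alpha * tp_pos)
        + cb * np.exp(-beta * tp_pos)
        + cc * np.exp(-ka * tp_pos)
    )
    conc = scale * np.sum(np.where(active, contrib * amounts[None, :], 0.0), axis=1)
    return conc.reshape(out_shape)


def auc_tau(ind: IndividualParameters, daily_dose: float) -> float:
    """Steady-state AUC over one 24 h dosing interval, in ng·h/ml.

    Equals bioavailable dose over clearance:
    ``f * dose [mg] / cl [l/h]`` = mg·h/l, times 1000 to reach ng·h/ml.
    """
    if daily_dose <= 0:
        raise InvalidInputError("daily_dose must be > 0")
    return MG_PER_L_TO_NG_PER_ML * ind.f * daily_dose / ind.cl


def cycle_day15_predose_time(cycle: int) -> float:
    """Hours since first dose at which the day-15 dose of ``cycle`` is due."""
    return ((cycle - 1) * CYCLE_LENGTH_DAYS + 14) * 24.0


def predict_cmin(
    ind: IndividualParameters, doses: Sequence[DoseEvent], cycle: int
) -> float:
    """Trough concentration of the given cycle: the model prediction
    immediately before the day-15 dose (24 h after the day-14 dose),
    accounting for the full preceding dose history.
    """
    t_trough = cycle_day15_predose_time(cycle)
    cycle_start = (cycle - 1) * CYCLE_LENGTH_DAYS * 24.0
    n_in_cycle = sum(1 for d in doses if cycle_start <= d.time < t_trough)
    if n_in_cycle < 14:
        raise MissingCycleError(
            f"cycle {cycle}: need >= 14 dosing days before the day-15 trough, "
            f"found {n_in_cycle}"
        )
    history = [d for d in doses if d.time < t_trough]
    return float(concentration_profile(ind, history, np.array([t_trough]))[0])
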