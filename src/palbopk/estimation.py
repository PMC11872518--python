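"""Nonlinear mixed-effects estimation with a frequentist prior penalty.

The population model is hierarchical: log-normal between-subject random
effects eta ~ N(0, Omega) on selected PK parameters, and a proportional
(plus optional additive) residual error on concentrations. With one or two
samples per patient the marginal likelihood alone cannot identify all fixed
effects, so the total objective adds a normal penalty centred on a previous
model's published estimates — the pharmacometric "frequentist prior"
technique. Parameters may be flagged as carrying no prior weight (e.g. a
formulation effect being tested), in which case the data alone inform them.

Estimation method: the marginal likelihood of each subject is approximated
by the Laplace method at the empirical-Bayes mode of eta (with interaction:
the residual variance depends on the individual prediction). The population
objective function value (OFV) is -2 times the penalized marginal
log-likelihood; differences in OFV between nested models are treated as
chi-square, with a drop of >= 3.84 points (1 df) declared significant at
P < 0.05.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .pkmodel import (
    MG_PER_L_TO_NG_PER_ML,
    ALLOMETRIC_EXPONENTS,
    IndividualParameters,
    PopulationParameters,
    SubjectRecord,
    individual_from_eta,
)

__all__ = [
    "ConfigurationError",
    "PriorSpecification",
    "FitConfig",
    "FitResult",
    "LRT_THRESHOLD",
    "prior_penalty",
    "individual_objective",
    "estimate_individual",
    "marginal_ofv",
    "fit_population",
    "lrt_covariate",
]

logger = logging.getLogger(__name__)

#: Chi-square(1 df) critical value at P = 0.05 for the likelihood-ratio test.
LRT_THRESHOLD = 3.84

_LOG_2PI = float(np.log(2.0 * np.pi))

#: Structural fixed-effect names, in canonical order.
STRUCTURAL_NAMES = ("cl_pop", "v1_pop", "v2_pop", "q_pop", "ka", "tlag", "f_rel")

#: Variance floor (ng/ml)^2 guarding against zero residual variance at a
#: zero model prediction with proportional-only error.
_VAR_FLOOR = 1e-12


class ConfigurationError(ValueError):
    """Raised for inconsistent estimation settings (singular matrices etc.)."""


# ---------------------------------------------------------------------------
# Prior specification and penalty
# ---------------------------------------------------------------------------

@dataclass
class PriorSpecification:
    """Normal prior on fixed effects, on the natural parameter scale.

    ``names`` selects the structural parameters the prior covers (aligned
    with ``theta_prior`` / ``theta_prior_cov``). ``weight_flags`` marks which
    of those actually carry prior weight; unflagged parameters contribute
    nothing to the penalty. The covariance is typically diagonal, built from
    published relative standard errors via ``sd = rse * mean``.
    """

    names: Tuple[str, ...]
    theta_prior: np.ndarray
    theta_prior_cov: np.ndarray
    weight_flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    omega_prior: Optional[np.ndarray] = None
    omega_dof: Optional[float] = None

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.theta_prior = np.asarray(self.theta_prior, dtype=float)
        self.theta_prior_cov = np.atleast_2d(np.asarray(self.theta_prior_cov, dtype=float))
        k = len(self.names)
        if self.theta_prior.shape != (k,):
            raise ConfigurationError("theta_prior length must match names")
        if self.theta_prior_cov.shape != (k, k):
            raise ConfigurationError("theta_prior_cov must be square, matching names")
        if self.weight_flags is None:
            self.weight_flags = np.ones(k, dtype=bool)
        self.weight_flags = np.asarray(self.weight_flags, dtype=bool)
        if self.weight_flags.shape != (k,):
            raise ConfigurationError("weight_flags length must match names")
        w = self.weight_flags
        if w.any():
            sub = self.theta_prior_cov[np.ix_(w, w)]
            if not np.allclose(sub, sub.T):
                raise ConfigurationError("prior covariance must be symmetric")
            if np.any(np.linalg.eigvalsh(sub) <= 0):
                raise ConfigurationError(
                    "prior covariance must be positive definite on weighted parameters"
                )

    @classmethod
    def from_rse(
        cls,
        means: Dict[str, float],
        rse: Dict[str, float],
        no_weight: Sequence[str] = (),
    ) -> "PriorSpecification":
        """Diagonal prior from means and relative standard errors (fractions).

        Parameters listed in ``no_weight`` are included with a nominal unit
        variance but flagged as unweighted, so they never contribute.
        """
        names = tuple(means)
        mu = np.array([means[n] for n in names], dtype=float)
        sd = np.array([rse.get(n, 1.0) * abs(means[n]) for n in names])
        flags = np.array([n not in set(no_weight) for n in names])
        sd = np.where(flags, sd, 1.0)
        if np.any(sd[flags] <= 0):
            raise ConfigurationError("prior SDs must be positive on weighted parameters")
        return cls(names=names, theta_prior=mu, theta_prior_cov=np.diag(sd**2),
                   weight_flags=flags)

    def scaled(self, factor: float) -> "PriorSpecification":
        """A copy with the prior covariance multiplied by ``factor``."""
        return replace(self, theta_prior_cov=self.theta_prior_cov * factor)


def prior_penalty(theta: Sequence[float], prior: PriorSpecification) -> float:
    """Quadratic prior penalty (theta - mu)' Sigma^-1 (theta - mu).

    ``theta`` is aligned with ``prior.names``; only prior-weighted components
    enter. Zero iff theta equals the prior mean on all weighted components.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (len(prior.names),):
        raise ConfigurationError("theta length must match prior.names")
    w = prior.weight_flags
    if not w.any():
        return 0.0
    d = (theta - prior.theta_prior)[w]
    cov = prior.theta_prior_cov[np.ix_(w, w)]
    try:
        sol = np.linalg.solve(cov, d)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("singular prior covariance") from exc
    return float(d @ sol)


def _theta_from_pop(pop: PopulationParameters, names: Sequence[str]) -> np.ndarray:
    return np.array([getattr(pop, n) for n in names], dtype=float)


# ---------------------------------------------------------------------------
# Per-subject likelihood machinery
# ---------------------------------------------------------------------------

class _SubjectModel:
    """Precomputed fast path for one subject's predictions and objective.

    Avoids rebuilding dataclasses inside the inner (eta) and outer (theta)
    optimisation loops; semantics are identical to building
    ``IndividualParameters`` via :func:`individual_from_eta` and calling
    ``concentration_profile``.
    """

    def __init__(self, subject: SubjectRecord, pop: PopulationParameters):
        self.subject_id = subject.subject_id
        obs = subject.usable_observations
        self.n_obs = len(obs)
        self.y = np.array([o.value for o in obs], dtype=float)
        self.t_obs = np.array([o.time for o in obs], dtype=float)
        self.dose_times = np.array([d.time for d in subject.doses], dtype=float)
        self.amounts = np.array([d.amount for d in subject.doses], dtype=float)
        self.is_tablet = subject.formulation == "tablet"
        w = subject.weight / pop.wt_ref
        # typical values after allometry
        self.typ = {
            "cl": pop.cl_pop * w ** ALLOMETRIC_EXPONENTS["cl"],
            "v1": pop.v1_pop * w ** ALLOMETRIC_EXPONENTS["v1"],
            "v2": pop.v2_pop * w ** ALLOMETRIC_EXPONENTS["v2"],
            "q": pop.q_pop * w ** ALLOMETRIC_EXPONENTS["q"],
            "ka": pop.ka,
            "f": pop.f_rel if self.is_tablet else 1.0,
        }
        self.tlag = pop.tlag
        self.omega_names = pop.omega_names
        self.sigma_prop2 = pop.sigma_prop**2
        self.sigma_add2 = pop.sigma_add**2
        sign, logdet = np.linalg.slogdet(pop.omega)
        if sign <= 0:
            raise ConfigurationError("omega is singular or not positive definite")
        self.omega_logdet = float(logdet)
        self.omega_inv = np.linalg.inv(pop.omega)

    def predict(self, eta: np.ndarray) -> np.ndarray:
        """Model concentrations at the usable observation times."""
        p = dict(self.typ)
        for name, e in zip(self.omega_names, eta):
            p[name] = p[name] * np.exp(e)
        k10 = p["cl"] / p["v1"]
        k12 = p["q"] / p["v1"]
        k21 = p["q"] / p["v2"]
        s = k10 + k12 + k21
        disc = np.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
        alpha = 0.5 * (s + disc)
        beta = 0.5 * (s - disc)
        ka = p["ka"]
        while abs(ka - alpha) < 1e-8 * ka or abs(ka - beta) < 1e-8 * ka:
            ka *= 1.0 + 1e-8
        ca = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
        cb = (k21 - beta) / ((ka - beta) * (alpha - beta))
        cc = (k21 - ka) / ((alpha - ka) * (beta - ka))
        scale = MG_PER_L_TO_NG_PER_ML * p["f"] * ka / p["v1"]
        tp = self.t_obs[:, None] - self.dose_times[None, :] - self.tlag
        active = tp > 0
        tp = np.where(active, tp, 0.0)
        contrib = ca * np.exp(-alpha * tp) + cb * np.exp(-beta * tp) + cc * np.exp(-ka * tp)
        return scale * np.sum(np.where(active, contrib * self.amounts[None, :], 0.0), axis=1)

    def objective(self, eta: np.ndarray) -> float:
        """-2 log of (residual likelihood x eta prior), dropping constants:
        sum[(y-f)^2/var + log var] + eta' Omega^-1 eta."""
        val = float(eta @ self.omega_inv @ eta)
        if self.n_obs:
            f = self.predict(eta)
            var = np.maximum(self.sigma_prop2 * f * f + self.sigma_add2, _VAR_FLOOR)
            r = self.y - f
            val += float(np.sum(r * r / var + np.log(var)))
        return val


def _grad_hess(fun: Callable[[np.ndarray], float], x: np.ndarray, h: float = 1e-4
               ) -> Tuple[float, np.ndarray, np.ndarray]:
    """Central-difference value, gradient and Hessian of a scalar function."""
    d = len(x)
    f0 = fun(x)
    g = np.zeros(d)
    H = np.zeros((d, d))
    fp = np.zeros(d)
    fm = np.zeros(d)
    for i in range(d):
        e = np.zeros(d)
        e[i] = h
        fp[i] = fun(x + e)
        fm[i] = fun(x - e)
        g[i] = (fp[i] - fm[i]) / (2 * h)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
    for i in range(d):
        for j in range(i + 1, d):
            e = np.zeros(d)
            e[i] = h
            e[j] = h
            fpp = fun(x + e)
            fmm = fun(x - e)
            H[i, j] = H[j, i] = (fpp - 2 * f0 + fmm - H[i, i] * h**2 - H[j, j] * h**2) / (2 * h**2)
    return f0, g, H


def _newton_minimize(
    fun: Callable[[np.ndarray], float],
    x0: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 60,
) -> Tuple[np.ndarray, float, np.ndarray, bool]:
    """Damped Newton minimisation with numeric derivatives.

    Returns (x, f(x), Hessian at x, converged). The Hessian is reused by the
    Laplace approximation, so it is always evaluated at the returned point.
    """
    x = np.asarray(x0, dtype=float).copy()
    f0, g, H = _grad_hess(fun, x)
    converged = False
    for _ in range(max_iter):
        # regularize the Hessian to be positive definite for the step
        try:
            evals = np.linalg.eigvalsh(H)
            lam = max(0.0, 1e-8 - float(evals.min()))
        except np.linalg.LinAlgError:
            lam = 1.0
        try:
            step = np.linalg.solve(H + lam * np.eye(len(x)), g)
        except np.linalg.LinAlgError:
            step = g
        if not np.all(np.isfinite(step)):
            step = g
        # cap the step: eta is log-scale, steps beyond ~2 are meaningless and
        # can overflow the model when the local curvature is negative
        norm = float(np.linalg.norm(step))
        if norm > 2.0:
            step = step * (2.0 / norm)
        # backtracking line search
        t = 1.0
        f_new = None
        for _ in range(25):
            x_new = x - t * step
            f_try = fun(x_new)
            if np.isfinite(f_try) and f_try <= f0 + 1e-12:
                f_new = f_try
                break
            t *= 0.5
        if f_new is None:
            break
        moved = np.max(np.abs(t * step))
        x = x_new
        f_prev = f0
        f0, g, H = _grad_hess(fun, x)
        if moved < 1e-9 or (f_prev - f0 < tol * (1.0 + abs(f0)) and np.max(np.abs(g)) < 1e-4):
            converged = True
            break
    return x, f0, H, converged


# ---------------------------------------------------------------------------
# Public per-subject operations
# ---------------------------------------------------------------------------

def individual_objective(
    subject: SubjectRecord, pop: PopulationParameters, eta: Sequence[float]
) -> float:
    """MAP objective for one subject at the given random effects.

    Sum of weighted squared residuals with their log-variance terms
    (proportional + additive error, evaluated at the individual prediction)
    plus the shrinkage term eta' Omega^-1 eta. Equals eta' Omega^-1 eta when
    the subject has no usable (non-BLQ) observations.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (len(pop.omega_names),):
        raise ConfigurationError(f"eta must have length {len(pop.omega_names)}")
    return _SubjectModel(subject, pop).objective(eta)


def estimate_individual(
    subject: SubjectRecord,
    pop: PopulationParameters,
    eta0: Optional[np.ndarray] = None,
) -> IndividualParameters:
    """Empirical-Bayes (MAP) individual parameters for one subject.

    Minimises :func:`individual_objective` over eta; with no usable
    observations the mode is eta = 0 (the population prior). A failed
    optimisation is flagged via ``converged=False``, never silent.
    """
    d = len(pop.omega_names)
    model = _SubjectModel(subject, pop)
    if model.n_obs == 0:
        return individual_from_eta(pop, subject.weight, np.zeros(d), subject.formulation)
    x0 = np.zeros(d) if eta0 is None else np.asarray(eta0, dtype=float)
    eta_hat, f_hat, _, ok = _newton_minimize(model.objective, x0)
    if not ok:
        for start in _eta_starts(d):
            cand, f_c, _, ok_c = _newton_minimize(model.objective, start)
            if f_c < f_hat - 1e-9:
                eta_hat, f_hat, ok = cand, f_c, ok_c
    if not ok:
        res = optimize.minimize(model.objective, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if res.fun <= model.objective(eta_hat):
            eta_hat = res.x
        ok = res.success
    ind = individual_from_eta(pop, subject.weight, eta_hat, subject.formulation)
    ind.converged = bool(ok)
    if not ok:
        logger.warning("EBE optimisation did not converge for subject %s",
                       subject.subject_id)
    return ind


def _eta_starts(d: int) -> list:
    """Fixed fallback start points spanning plausible log-scale effects."""
    starts = [np.full(d, v) for v in (-1.5, -0.75, 0.75, 1.5)]
    if d > 1:
        eye = np.eye(d)
        starts += [1.0 * eye[i] for i in range(d)]
        starts += [-1.0 * eye[i] for i in range(d)]
    return starts


def _laplace_subject_ofv(model: _SubjectModel, eta0: np.ndarray
                         ) -> Tuple[float, np.ndarray]:
    """-2 log marginal likelihood of one subject by the Laplace method.

    With h(eta) = objective(eta) + n log(2 pi) + log det(2 pi Omega), the
    Laplace approximation of -2 log integral exp(-h/2) d eta collapses to
    objective(eta_hat) + n log(2 pi) + log det(Omega) + log det(H), where
    H is half the Hessian of the objective at the mode. Exact when the
    objective is quadratic in eta (model linear in eta, additive error).
    """
    d = len(eta0)
    if model.n_obs == 0:
        return 0.0, np.zeros(d)
    eta_hat, f_hat, H_obj, ok = _newton_minimize(model.objective, eta0)
    if not ok:
        # safeguard against a missed mode: deterministic multistart from a
        # coarse spread of eta values, keeping the best Newton endpoint
        for start in _eta_starts(d):
            cand, f_c, H_c, _ = _newton_minimize(model.objective, start)
            if f_c < f_hat - 1e-9:
                eta_hat, f_hat, H_obj = cand, f_c, H_c
    H = 0.5 * H_obj
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        # mode Hessian not PD (flat or saddle direction): floor eigenvalues
        evals, vecs = np.linalg.eigh(H)
        evals = np.maximum(evals, 1e-10)
        logdet = float(np.sum(np.log(evals)))
    ofv = f_hat + model.n_obs * _LOG_2PI + model.omega_logdet + float(logdet)
    return ofv, eta_hat


def marginal_ofv(
    dataset: Sequence[SubjectRecord],
    pop: PopulationParameters,
    prior: Optional[PriorSpecification] = None,
    _eta_cache: Optional[Dict[str, np.ndarray]] = None,
) -> float:
    """Population objective function value: -2 penalized marginal log-likelihood.

    Laplace-approximated subject marginals summed over the dataset, plus the
    prior penalty on the fixed effects. Deterministic given inputs.
    """
    if not any(len(s.usable_observations) for s in dataset):
        raise ConfigurationError("need at least one subject with usable observations")
    d = len(pop.omega_names)
    total = 0.0
    for subject in dataset:
        model = _SubjectModel(subject, pop)
        eta0 = np.zeros(d)
        if _eta_cache is not None:
            eta0 = _eta_cache.get(subject.subject_id, eta0)
        ofv_i, eta_hat = _laplace_subject_ofv(model, eta0)
        if not np.isfinite(ofv_i):
            raise ConfigurationError(
                f"non-finite marginal likelihood for subject {subject.subject_id}"
            )
        if _eta_cache is not None:
            _eta_cache[subject.subject_id] = eta_hat
        total += ofv_i
    if prior is not None:
        total += prior_penalty(_theta_from_pop(pop, prior.names), prior)
    return total


# ---------------------------------------------------------------------------
# Population fit
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Settings for the population fit.

    ``estimate_theta`` lists the structural fixed effects estimated (others
    stay at their initial values); the diagonal of omega and the residual
    SDs are estimated when flagged. All free parameters are optimised on the
    log scale, so positivity is structural.
    """

    estimate_theta: Tuple[str, ...] = ("cl_pop", "v1_pop", "v2_pop", "q_pop")
    estimate_omega: bool = True
    estimate_sigma_prop: bool = True
    estimate_sigma_add: bool = False
    n_starts: int = 5  # total attempts: initial + up to 4 perturbed restarts
    perturb_sd: float = 0.15  # log-scale SD of restart perturbations
    seed: int = 20170301  # fixed seed for restart perturbations
    maxiter: int = 200
    tol: float = 1e-6  # relative OFV convergence tolerance
    compute_covariance: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.estimate_theta) - set(STRUCTURAL_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown structural parameters: {sorted(unknown)}")


@dataclass
class FitResult:
    """Outcome of a population fit."""

    estimates: PopulationParameters
    ofv: float
    covariance: Optional[np.ndarray]  # log-scale, aligned with free_names
    rse: Dict[str, float]  # percent, per free parameter
    converged: bool
    n_subjects: int
    n_obs: int
    free_names: Tuple[str, ...] = ()
    n_starts_used: int = 1

    def to_dict(self) -> dict:
        est = self.estimates
        return {
            "converged": self.converged,
            "ofv": self.ofv,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
            "n_starts_used": self.n_starts_used,
            "estimates": {
                "cl_pop": est.cl_pop, "v1_pop": est.v1_pop, "v2_pop": est.v2_pop,
                "q_pop": est.q_pop, "ka": est.ka, "tlag": est.tlag,
                "f_rel": est.f_rel,
                "omega_diag": np.diag(est.omega).tolist(),
                "omega_names": list(est.omega_names),
                "sigma_prop": est.sigma_prop, "sigma_add": est.sigma_add,
            },
            "rse_percent": self.rse,
        }


def _build_pop(init: PopulationParameters, free_names: Sequence[str],
               x: np.ndarray) -> PopulationParameters:
    """Population parameters from log-scale free vector ``x``."""
    values = dict(zip(free_names, np.exp(x)))
    kwargs = {}
    for name in STRUCTURAL_NAMES:
        if name in values:
            kwargs[name] = values[name]
    omega = init.omega.copy()
    for i, oname in enumerate(init.omega_names):
        key = f"omega_{oname}"
        if key in values:
            omega[i, i] = values[key]
    kwargs["omega"] = omega
    if "sigma_prop" in values:
        kwargs["sigma_prop"] = values["sigma_prop"]
    if "sigma_add" in values:
        kwargs["sigma_add"] = values["sigma_add"]
    return replace(init, **kwargs)


def fit_population(
    dataset: Sequence[SubjectRecord],
    init: PopulationParameters,
    prior: Optional[PriorSpecification] = None,
    config: Optional[FitConfig] = None,
) -> FitResult:
    """Fit the population model by penalized Laplace maximum likelihood.

    Quasi-Newton (L-BFGS-B) optimisation of the marginal OFV over
    log-transformed free parameters, with empirical-Bayes warm starts
    carried across objective evaluations. On non-convergence the fit is
    restarted from perturbed initials (up to ``config.n_starts`` attempts,
    seeded); if no attempt converges, the best point is returned with
    ``converged=False``.
    """
    if not dataset:
        raise ConfigurationError("dataset must be non-empty")
    config = config or FitConfig()
    free_names = list(config.estimate_theta)
    if config.estimate_omega:
        free_names += [f"omega_{n}" for n in init.omega_names]
    if config.estimate_sigma_prop:
        free_names.append("sigma_prop")
    if config.estimate_sigma_add:
        free_names.append("sigma_add")
    if not free_names:
        raise ConfigurationError("no free parameters to estimate")

    def x_init_from(pop: PopulationParameters) -> np.ndarray:
        vals = []
        for name in free_names:
            if name.startswith("omega_"):
                i = pop.omega_names.index(name[len("omega_"):])
                vals.append(pop.omega[i, i])
            else:
                vals.append(getattr(pop, name))
        return np.log(np.asarray(vals, dtype=float))

    eta_cache: Dict[str, np.ndarray] = {}

    def objective(x: np.ndarray) -> float:
        try:
            pop = _build_pop(init, free_names, x)
            return marginal_ofv(dataset, pop, prior, _eta_cache=eta_cache)
        except (ConfigurationError, FloatingPointError, np.linalg.LinAlgError):
            return 1e12

    rng = np.random.default_rng(config.seed)
    x0_base = x_init_from(init)
    best: Optional[optimize.OptimizeResult] = None
    n_used = 0
    for attempt in range(max(1, config.n_starts)):
        x0 = x0_base if attempt == 0 else x0_base + rng.normal(0.0, config.perturb_sd,
                                                               size=len(x0_base))
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B",
            options={"maxiter": config.maxiter, "ftol": config.tol,
                     "gtol": 1e-6, "eps": 1e-5},
        )
        n_used = attempt + 1
        if best is None or res.fun < best.fun:
            best = res
        if res.success and np.isfinite(res.fun):
            best = res if res.fun <= best.fun else best
            break
        logger.info("fit attempt %d did not converge (status %s); restarting",
                    attempt + 1, res.message)
    assert best is not None
    converged = bool(best.success and np.isfinite(best.fun))
    x_hat = best.x
    ofv_hat = float(best.fun)
    # guard against an uphill "optimum" (possible when init is already good)
    f_init = objective(x0_base)
    if f_init < ofv_hat:
        x_hat, ofv_hat = x0_base, f_init
    estimates = _build_pop(init, free_names, x_hat)

    cov = None
    rse: Dict[str, float] = {}
    if config.compute_covariance:
        cov, rse = _covariance_and_rse(objective, x_hat, free_names)

    n_obs = sum(len(s.usable_observations) for s in dataset)
    return FitResult(
        estimates=estimates, ofv=ofv_hat, covariance=cov, rse=rse,
        converged=converged, n_subjects=len(dataset), n_obs=n_obs,
        free_names=tuple(free_names), n_starts_used=n_used,
    )


def _covariance_and_rse(objective: Callable[[np.ndarray], float], x_hat: np.ndarray,
                        free_names: Sequence[str]) -> Tuple[Optional[np.ndarray],
                                                            Dict[str, float]]:
    """Asymptotic covariance (log scale) from the inverse numerical Hessian
    of OFV/2; RSE% of a log-normally distributed estimate is approximately
    100 x SD(log estimate)."""
    _, _, H_ofv = _grad_hess(objective, x_hat, h=5e-4)
    H_half = 0.5 * H_ofv
    try:
        evals = np.linalg.eigvalsh(H_half)
        if np.any(evals <= 0):
            raise np.linalg.LinAlgError("non-PD Hessian")
        cov = np.linalg.inv(H_half)
    except np.linalg.LinAlgError:
        # ill-conditioned fit: pseudo-inverse, negative directions -> inf RSE
        evals, vecs = np.linalg.eigh(H_half)
        inv_evals = np.where(evals > 1e-10, 1.0 / np.maximum(evals, 1e-10), np.inf)
        finite = np.isfinite(inv_evals)
        cov = (vecs[:, finite] * inv_evals[finite]) @ vecs[:, finite].T
        logger.warning("OFV Hessian not positive definite; RSEs from pseudo-inverse")
    sd_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
    rse = {name: float(100.0 * s) for name, s in zip(free_names, sd_log)}
    return cov, rse


def lrt_covariate(ofv_reduced: float, ofv_full: float,
                  threshold: float = LRT_THRESHOLD) -> Dict[str, object]:
    """Likelihood-ratio test for one extra parameter in a nested model.

    Significant iff the OFV drop (reduced minus full) is at least 3.84
    points, the chi-square(1) critical value at P < 0.05.
    """
    delta = float(ofv_reduced - ofv_full)
    if delta < -0.1:
        warnings.warn(
            f"full model has higher OFV than reduced by {-delta:.3f}; "
            "likely an optimizer artifact", RuntimeWarning, stacklevel=2,
        )
    return {"significant": delta >= threshold, "delta": delta}
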