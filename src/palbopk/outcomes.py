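"""Exposure-response and exposure-toxicity statistics.

Implements the analysis set used in the study: univariable Cox
proportional-hazards regression of progression-free survival on continuous
exposure (hazard ratio reported per 10 ng/ml of Cmin or per 100 ng*h/ml of
AUC, with 90% confidence intervals), median and first-quartile
dichotomizations, Kaplan-Meier curves, a restricted-mean-survival-time
comparison, and the chi-square test for trend in proportions
(Cochran-Armitage) of adverse-event and dose-reduction rates across
exposure quartiles.

Survival machinery (Cox partial likelihood with Efron tie handling,
product-limit estimator, RMST) is delegated to lifelines; the trend test is
implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import restricted_mean_survival_time
from scipy import stats

__all__ = [
    "OutcomeRecord",
    "TrendTable",
    "CoxResult",
    "trend_test",
    "cox_univariable",
    "km_curve",
    "rmst_difference",
    "dichotomized_analysis",
    "quartile_event_table",
]


@dataclass
class OutcomeRecord:
    """Clinical outcome row for one patient. AE flags cover the first
    3 months of treatment only; PFS is the composite progression/death
    event supplied by the data."""

    subject_id: str
    line: str  # "first" | "second"
    pfs_time: float  # days
    pfs_event: bool
    ae_grade34_any: bool = False
    ae_grade34_neutropenia: bool = False
    dose_reduction_ever: bool = False

    def __post_init__(self) -> None:
        if self.pfs_time < 0:
            raise ValueError("pfs_time must be >= 0")
        if self.line not in ("first", "second"):
            raise ValueError("line must be 'first' or 'second'")


@dataclass
class TrendTable:
    """Events/totals per ordered exposure group, with ordinal scores."""

    events: Tuple[int, ...]
    totals: Tuple[int, ...]
    scores: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.events = tuple(int(e) for e in self.events)
        self.totals = tuple(int(t) for t in self.totals)
        if not self.scores:
            self.scores = tuple(float(i + 1) for i in range(len(self.totals)))
        self.scores = tuple(float(s) for s in self.scores)
        if not (len(self.events) == len(self.totals) == len(self.scores)):
            raise ValueError("events, totals and scores must have equal length")
        if len(self.totals) < 2:
            raise ValueError("trend test needs at least 2 groups")
        if any(t <= 0 for t in self.totals):
            raise ValueError("all group totals must be positive")
        if any(not 0 <= e <= t for e, t in zip(self.events, self.totals)):
            raise ValueError("events must satisfy 0 <= events <= totals")


@dataclass
class CoxResult:
    """Hazard ratio per ``unit_scale`` exposure units with its CI."""

    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int
    unit_scale: float = 1.0
    ci_level: float = 0.90
    beta: float = 0.0  # log-hazard per 1 exposure unit
    se_beta: float = 0.0

    def to_dict(self) -> dict:
        return {"hr": self.hr, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "p": self.p, "n": self.n, "n_events": self.n_events,
                "unit_scale": self.unit_scale, "ci_level": self.ci_level}


def trend_test(table: TrendTable) -> Dict[str, float]:
    """Cochran-Armitage chi-square test for trend in proportions.

    Equally spaced scores by default, no continuity correction, 1 degree of
    freedom, two-sided p-value — the construction of R's
    ``prop.trend.test``. Degenerate tables (no events anywhere, or events
    everywhere) carry no trend information: chi2 = 0, p = 1, with a warning.
    """
    e = np.asarray(table.events, dtype=float)
    n = np.asarray(table.totals, dtype=float)
    x = np.asarray(table.scores, dtype=float)
    p_bar = e.sum() / n.sum()
    if p_bar in (0.0, 1.0):
        warnings.warn("all-zero or all-full trend table; no trend testable",
                      RuntimeWarning, stacklevel=2)
        return {"chi2": 0.0, "p": 1.0}
    num = float(e @ x - p_bar * (n @ x))
    den = float(p_bar * (1.0 - p_bar) * (n @ x**2 - (n @ x) ** 2 / n.sum()))
    if den <= 0:
        warnings.warn("degenerate scores in trend table", RuntimeWarning,
                      stacklevel=2)
        return {"chi2": 0.0, "p": 1.0}
    chi2 = num * num / den
    return {"chi2": chi2, "p": float(stats.chi2.sf(chi2, df=1))}


def cox_univariable(
    data: pd.DataFrame,
    exposure_col: str,
    time_col: str = "pfs_time",
    event_col: str = "pfs_event",
    unit_scale: float = 1.0,
    ci_level: float = 0.90,
    ties: str = "efron",
) -> CoxResult:
    """Univariable Cox regression of survival on a continuous exposure.

    The hazard ratio is reported per ``unit_scale`` exposure units
    (e.g. 10 for "per 10 ng/ml"): hr = exp(beta * unit_scale), with a Wald
    CI at ``ci_level`` transformed on the same scale.
    """
    df = data[[time_col, event_col, exposure_col]].dropna().copy()
    df[event_col] = df[event_col].astype(int)
    n_events = int(df[event_col].sum())
    if n_events < 2:
        raise ValueError(f"Cox regression needs >= 2 events, got {n_events}")
    if float(np.std(df[exposure_col])) == 0.0:
        raise ValueError("exposure is constant; Cox coefficient not identifiable")
    if ties != "efron":
        raise ValueError("only Efron tie handling is supported")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col=time_col, event_col=event_col)
    beta = float(cph.params_[exposure_col])
    se = float(cph.standard_errors_[exposure_col])
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return CoxResult(
        hr=float(np.exp(beta * unit_scale)),
        ci_low=float(np.exp((beta - z * se) * unit_scale)),
        ci_high=float(np.exp((beta + z * se) * unit_scale)),
        p=p, n=len(df), n_events=n_events,
        unit_scale=unit_scale, ci_level=ci_level, beta=beta, se_beta=se,
    )


@dataclass
class KmCurve:
    """Product-limit survival estimate with censoring marks."""

    times: np.ndarray  # event/censor times (sorted, unique)
    survival: np.ndarray  # S(t) just after each time
    censor_times: np.ndarray = field(default_factory=lambda: np.array([]))
    n: int = 0

    def at(self, t: float) -> float:
        """Survival probability at time ``t`` (right-continuous step)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(times: Sequence[float], events: Sequence[bool]) -> KmCurve:
    """Kaplan-Meier estimate of the survival function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValueError("km_curve needs at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = t > 0  # lifelines includes the t=0 anchor row
    return KmCurve(times=t[keep], survival=s[keep],
                   censor_times=np.sort(times[~events]), n=len(times))


def rmst_difference(
    data: pd.DataFrame,
    group_col: str,
    tau: float,
    time_col: str = "pfs_time",
    event_col: str = "pfs_event",
    ci_level: float = 0.90,
) -> Dict[str, object]:
    """Restricted mean survival time per group and their difference.

    RMST is the area under the Kaplan-Meier curve up to the horizon ``tau``
    (which must not exceed the follow-up of either group); the difference
    carries a large-sample normal CI.
    """
    groups = sorted(data[group_col].dropna().unique().tolist())
    if len(groups) != 2:
        raise ValueError(f"rmst_difference needs exactly 2 groups, got {groups}")
    out: Dict[str, object] = {"tau": float(tau), "groups": groups}
    rmsts, variances = [], []
    for g in groups:
        sub = data[data[group_col] == g]
        if tau > float(sub[time_col].max()):
            raise ValueError(
                f"tau={tau} exceeds the last observed time in group {g!r}")
        kmf = KaplanMeierFitter().fit(sub[time_col], sub[event_col].astype(int))
        rmst, var = restricted_mean_survival_time(kmf, t=tau, return_variance=True)
        rmsts.append(float(rmst))
        variances.append(float(var))
    diff = rmsts[0] - rmsts[1]
    se = float(np.sqrt(variances[0] + variances[1]))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    out.update({
        "rmst_a": rmsts[0], "rmst_b": rmsts[1], "diff": diff,
        "ci": (diff - z * se, diff + z * se), "ci_level": ci_level,
    })
    return out


def dichotomized_analysis(
    data: pd.DataFrame,
    exposure_col: str,
    cut: str = "median",
    time_col: str = "pfs_time",
    event_col: str = "pfs_event",
    ci_level: float = 0.90,
) -> CoxResult:
    """Cox regression on exposure split at the median or the first quartile.

    The binary covariate is 1 for exposure at or above the cut (consistent
    with the boundary-goes-upward quartile rule); the HR therefore compares
    the high-exposure stratum with the low one.
    """
    if cut not in ("median", "q1"):
        raise ValueError("cut must be 'median' or 'q1'")
    df = data[[time_col, event_col, exposure_col]].dropna().copy()
    threshold = float(np.quantile(df[exposure_col], 0.5 if cut == "median" else 0.25))
    df["above"] = (df[exposure_col] >= threshold).astype(int)
    if df["above"].nunique() < 2:
        raise ValueError(f"empty stratum at the {cut} cut ({threshold:.3g})")
    return cox_univariable(df, "above", time_col=time_col, event_col=event_col,
                           unit_scale=1.0, ci_level=ci_level)


def quartile_event_table(quartiles: Sequence[Optional[int]],
                         flags: Sequence[bool],
                         scores: Sequence[float] = (1, 2, 3, 4)) -> TrendTable:
    """Events/totals per exposure quartile for a binary outcome flag.

    Rows with no quartile label (excluded patients) are dropped.
    """
    q = pd.Series(quartiles, dtype="float")
    f = pd.Series([bool(x) for x in flags])
    keep = q.notna()
    q, f = q[keep].astype(int), f[keep]
    events = tuple(int(f[q == k].sum()) for k in (1, 2, 3, 4))
    totals = tuple(int((q == k).sum()) for k in (1, 2, 3, 4))
    return TrendTable(events=events, totals=totals, scores=tuple(scores))
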