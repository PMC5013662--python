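"""Survival estimation and comparison: Kaplan–Meier curves, log-rank tests,
Cox proportional-hazards fits, 5-year-survival chi-square, and
treatment-stratified hazard tables.

Cox fits use Efron tie handling (lifelines' default), Wald confidence
intervals and p-values.  Endpoint labels are metadata only; mixing endpoints
in one comparison is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

COHORT_FLOOR = 30

ENDPOINTS = ("OS", "DFS", "RFS", "DMFS", "FP", "PFS", "relapse")


class FitFailureError(RuntimeError):
    """Cox partial-likelihood maximization failed (non-convergence/separation)."""


class UndefinedTestError(ValueError):
    """Test statistic undefined for the given data (e.g. zero events)."""


def _as_time_event(
    time: Sequence[float] | pd.Series, event: Sequence[int] | pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event)
    if (t < 0).any():
        raise ValueError("negative follow-up time")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return t, e.astype(int)


@dataclass
class KMResult:
    """Product-limit estimate with a risk table at each event time."""

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # risk-set size at each event time
    n_events: np.ndarray       # events at each event time
    n: int

    def survival_at(self, t: float) -> float:
        """Right-continuous step evaluation of S(t); S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.n_events,
            }
        )


def km_estimate(time, event) -> KMResult:
    """Kaplan–Meier product-limit estimator; censored subjects leave the risk
    set after their censoring time."""
    t, e = _as_time_event(time, event)
    if t.size == 0:
        raise ValueError("no records")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        return KMResult(
            times=np.array([]),
            survival=np.array([]),
            at_risk=np.array([]),
            n_events=np.array([]),
            n=t.size,
        )
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = np.array([(t >= et).sum() for et in event_times])
    n_ev = np.array([((t == et) & (e == 1)).sum() for et in event_times])
    return KMResult(
        times=event_times, survival=surv, at_risk=at_risk, n_events=n_ev, n=t.size
    )


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    df: int
    n: int
    n_events: int


def logrank_test(time, event, groups) -> LogrankResult:
    """k-group log-rank test (observed vs expected over pooled event times)."""
    t, e = _as_time_event(time, event)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if labels.size < 2:
        raise ValueError("need at least 2 non-empty groups")
    if e.sum() < 1:
        raise UndefinedTestError("log-rank undefined with zero events")
    res = multivariate_logrank_test(t, g, e)
    return LogrankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        df=int(labels.size - 1),
        n=int(t.size),
        n_events=int(e.sum()),
    )


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald CIs and p-values."""

    table: pd.DataFrame        # index: covariate; coef, hr, ci_low, ci_high, se, p
    log_likelihood: float
    n: int
    n_events: int
    tie_handling: str = "efron"

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.table.loc[covariate]
        return float(row["ci_low"]), float(row["ci_high"])

    def p(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "p"])


def cox_fit(
    data: pd.DataFrame,
    covariates: Sequence[str],
    time_col: str = "time",
    event_col: str = "event",
    reference_levels: dict[str, str] | None = None,
) -> CoxResult:
    """Multivariate Cox proportional-hazards fit (Efron tie handling).

    Categorical covariates are expanded to indicators against a reference
    level (lowest-coded by default, configurable via ``reference_levels``).
    """
    reference_levels = reference_levels or {}
    df = data[[time_col, event_col, *covariates]].copy()
    _as_time_event(df[time_col], df[event_col])

    design = pd.DataFrame(index=df.index)
    for cov in covariates:
        col = df[cov]
        if pd.api.types.is_numeric_dtype(col) and not isinstance(
            col.dtype, pd.CategoricalDtype
        ):
            design[cov] = col.astype(float)
        else:
            levels = sorted(col.astype(str).unique())
            ref = str(reference_levels.get(cov, levels[0]))
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not in {cov!r} levels")
            for lev in levels:
                if lev != ref:
                    design[f"{cov}[{lev}]"] = (col.astype(str) == lev).astype(float)
    for name in design.columns:
        if design[name].nunique() < 2:
            raise ValueError(f"covariate {name!r} is constant")
    n_events = int(df[event_col].sum())
    if n_events < design.shape[1]:
        raise ValueError(
            f"events ({n_events}) fewer than fitted parameters ({design.shape[1]})"
        )

    fit_df = pd.concat([df[[time_col, event_col]], design], axis=1)
    cph = CoxPHFitter()
    try:
        cph.fit(fit_df, duration_col=time_col, event_col=event_col)
    except (ConvergenceError, ValueError) as exc:
        raise FitFailureError(f"Cox fit failed: {exc}") from exc

    summ = cph.summary
    table = pd.DataFrame(
        {
            "coef": summ["coef"],
            "hr": summ["exp(coef)"],
            "ci_low": summ["exp(coef) lower 95%"],
            "ci_high": summ["exp(coef) upper 95%"],
            "se": summ["se(coef)"],
            "p": summ["p"],
        }
    )
    if not np.isfinite(table[["coef", "se"]].to_numpy()).all():
        raise FitFailureError(f"non-finite Cox estimates:\n{table}")
    return CoxResult(
        table=table,
        log_likelihood=float(cph.log_likelihood_),
        n=int(fit_df.shape[0]),
        n_events=n_events,
    )


@dataclass
class FiveYearResult:
    proportions: dict[str, float]   # group label -> surviving fraction
    counts: pd.DataFrame            # 2x2: group × {surviving, not_surviving}
    statistic: float
    p_value: float
    n_excluded: dict[str, int]      # censored before the horizon, per group


def five_year_survival_test(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    horizon: float = 5.0,
    labels: tuple[str, str] = ("A", "B"),
    time_col: str = "time",
    event_col: str = "event",
) -> FiveYearResult:
    """Chi-square comparison of fixed-horizon survival proportions.

    A subject is surviving if event-free with follow-up ≥ horizon, not
    surviving if the event occurred before the horizon, and excluded (counted)
    if censored before the horizon.
    """
    counts = {}
    excluded = {}
    props = {}
    for label, grp in zip(labels, (group_a, group_b)):
        t, e = _as_time_event(grp[time_col], grp[event_col])
        dead = ((e == 1) & (t < horizon)).sum()
        alive = (t >= horizon).sum()
        excluded[label] = int(((e == 0) & (t < horizon)).sum())
        if dead + alive == 0:
            raise ValueError(f"group {label!r} has no classifiable subjects")
        counts[label] = (int(alive), int(dead))
        props[label] = alive / (alive + dead)
    table = pd.DataFrame(counts, index=["surviving", "not_surviving"]).T
    obs = table.to_numpy()
    if (obs.sum(axis=0) == 0).any():
        stat, p = 0.0, 1.0
    else:
        stat, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return FiveYearResult(
        proportions=props,
        counts=table,
        statistic=float(stat),
        p_value=float(p),
        n_excluded=excluded,
    )


@dataclass
class ForestRow:
    label: str
    comparison: str
    n: int
    n_events: int
    hr: float
    ci_low: float
    ci_high: float
    cox_p: float
    logrank_p: float


@dataclass
class ForestTable:
    rows: list[ForestRow] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "label", "comparison", "n", "n_events",
            "hr", "ci_low", "ci_high", "cox_p", "logrank_p",
        ]
        return pd.DataFrame([vars(r) for r in self.rows], columns=cols)

    def row(self, label: str) -> ForestRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)


def stratified_treatment_analysis(
    cohort: pd.DataFrame,
    stratum_col: str = "stratum",
    treated_col: str = "treated",
    time_col: str = "time",
    event_col: str = "event",
    floor: int = COHORT_FLOOR,
) -> ForestTable:
    """Treatment-specific hazards of a binary score stratum (high vs low).

    Produces four analyses: treatment effect within the high and within the
    low stratum, and the high-vs-low hazard within the treated and untreated
    arms.  Each row carries the Cox HR/CI/p and the two-group log-rank p.
    Subcohorts below the size floor, or with an empty cell or no events, are
    dropped with a note.
    """
    out = ForestTable()
    strata = cohort[stratum_col].astype(str)
    treated = cohort[treated_col].astype(int)

    analyses = [
        ("treated_within_high", strata == "high", treated, "treated vs untreated"),
        ("treated_within_low", strata == "low", treated, "treated vs untreated"),
        ("high_within_treated", treated == 1, (strata == "high").astype(int), "high vs low"),
        ("high_within_untreated", treated == 0, (strata == "high").astype(int), "high vs low"),
    ]
    for label, mask, indicator, comparison in analyses:
        sub = cohort.loc[mask].copy()
        ind = indicator.loc[mask].astype(int)
        n = len(sub)
        if n < floor:
            out.dropped.append(f"{label}: n={n} below floor {floor}")
            continue
        if ind.nunique() < 2:
            out.dropped.append(f"{label}: a comparison cell is empty")
            continue
        if sub[event_col].sum() < 2:
            out.dropped.append(f"{label}: fewer than 2 events")
            continue
        sub["_x"] = ind.to_numpy()
        try:
            cox = cox_fit(sub, ["_x"], time_col=time_col, event_col=event_col)
        except (FitFailureError, ValueError) as exc:
            out.dropped.append(f"{label}: {exc}")
            continue
        lr = logrank_test(sub[time_col], sub[event_col], sub["_x"])
        out.rows.append(
            ForestRow(
                label=label,
                comparison=comparison,
                n=n,
                n_events=int(sub[event_col].sum()),
                hr=cox.hr("_x"),
                ci_low=cox.ci("_x")[0],
                ci_high=cox.ci("_x")[1],
                cox_p=cox.p("_x"),
                logrank_p=lr.p_value,
            )
        )
    return out
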