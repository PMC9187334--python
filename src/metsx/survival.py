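"""Cox proportional-hazards application stage and bivariate group tests.

Wraps lifelines' Cox partial-likelihood fitter (Efron tie handling by
default) with proportionality diagnostics from scaled Schoenfeld residuals,
plus the classical two-group comparisons used in the mortality table:
chi-square on counts (no continuity correction by default), two-sample t,
and Mood's median test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Cohort, DomainError, InsufficientDataError
from .scores import ScoreEquation, builtin_equation, evaluate

__all__ = ["CoxResult", "cox_fit", "compare_groups", "survival_report"]


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald CIs and proportionality checks."""

    names: list[str]
    hr: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p: dict[str, float]
    n: int
    events: int
    loglik: float
    prop_p: dict[str, float]
    prop_global_p: Optional[float]
    dropped: list[str] = field(default_factory=list)
    converged: bool = True

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "events": self.events,
            "log_likelihood": self.loglik,
            "covariates": {
                name: {
                    "hr": self.hr[name],
                    "ci": [self.ci_low[name], self.ci_high[name]],
                    "p": self.p[name],
                    "proportionality_p": self.prop_p.get(name),
                }
                for name in self.names
            },
            "proportionality_global_p": self.prop_global_p,
            "dropped": self.dropped,
            "converged": self.converged,
        }


def cox_fit(
    time: Sequence[float],
    event: Sequence[int],
    covariates: pd.DataFrame,
    ties: str = "efron",
    alpha: float = 0.05,
) -> CoxResult:
    """Fit a Cox proportional-hazards model.

    ``ties`` is "efron" (default) or "breslow".  Constant covariates are
    dropped with a warning entry; rows must be complete (complete-case).
    The proportional-hazards assumption is tested per covariate with the
    scaled-Schoenfeld-residual test; a global p is formed by summing the
    per-covariate chi-square statistics (approximate — components are
    correlated).
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError
    from lifelines.statistics import proportional_hazard_test

    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if np.any(time <= 0):
        raise DomainError("all survival times must be positive")
    if set(np.unique(event)) - {0, 1}:
        raise DomainError("event must be binary 0/1")
    if event.sum() == 0:
        raise DomainError("no events observed: Cox model cannot be fit")
    cov = covariates.astype(float).reset_index(drop=True)
    if cov.isna().any().any():
        raise DomainError("covariates contain missing values (complete-case only)")
    dropped = [c for c in cov.columns if cov[c].nunique() <= 1]
    cov = cov.drop(columns=dropped)
    if cov.shape[1] == 0:
        raise DomainError("no non-constant covariates left")

    if ties not in ("efron", "breslow"):
        raise DomainError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    names = list(cov.columns)
    if ties == "breslow":
        # lifelines only implements Efron ties; the Breslow approximation is
        # fit directly on its partial likelihood with a Wald covariance from
        # the numerical Hessian
        return _breslow_fit(time, event, cov, dropped, alpha)

    df = cov.copy()
    df["_time"] = time
    df["_event"] = event
    cph = CoxPHFitter(alpha=alpha)
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
        converged = True
    except ConvergenceError as exc:
        raise DomainError(f"Cox model failed to converge: {exc}") from exc

    summ = cph.summary
    hr = {c: float(summ.loc[c, "exp(coef)"]) for c in names}
    lo_col = f"exp(coef) lower {int((1 - alpha) * 100)}%"
    hi_col = f"exp(coef) upper {int((1 - alpha) * 100)}%"
    ci_low = {c: float(summ.loc[c, lo_col]) for c in names}
    ci_high = {c: float(summ.loc[c, hi_col]) for c in names}
    pvals = {c: float(summ.loc[c, "p"]) for c in names}

    prop = proportional_hazard_test(cph, df, time_transform="rank")
    psum = prop.summary
    prop_p = {c: float(psum.loc[c, "p"]) for c in names}
    stat_total = float(psum["test_statistic"].sum())
    prop_global_p = float(stats.chi2.sf(stat_total, df=len(names)))

    return CoxResult(
        names=names, hr=hr, ci_low=ci_low, ci_high=ci_high, p=pvals,
        n=len(df), events=int(event.sum()),
        loglik=float(cph.log_likelihood_),
        prop_p=prop_p, prop_global_p=prop_global_p,
        dropped=dropped, converged=converged,
    )


def _breslow_loglik(beta: np.ndarray, time: np.ndarray, event: np.ndarray,
                    X: np.ndarray) -> float:
    """Breslow-approximation partial log-likelihood."""
    order = np.argsort(time)
    t, d, Xs = time[order], event[order], X[order]
    eta = Xs @ beta
    # risk-set sums computed from the tail via reverse cumulative sums
    exp_eta = np.exp(eta)
    rev_cum = np.cumsum(exp_eta[::-1])[::-1]
    ll = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        dead = [k for k in range(i, j) if d[k] == 1]
        if dead:
            ll += eta[dead].sum() - len(dead) * math.log(rev_cum[i])
        i = j
    return ll


def _breslow_fit(time, event, cov: pd.DataFrame, dropped: list[str],
                 alpha: float) -> CoxResult:
    from scipy import optimize

    X = cov.to_numpy(dtype=float)
    names = list(cov.columns)
    k = X.shape[1]

    def nll(beta):
        return -_breslow_loglik(beta, time, event, X)

    res = optimize.minimize(nll, np.zeros(k), method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 500})
    beta = res.x
    # observed information via central finite differences of the gradient
    h = 1e-5
    H = np.zeros((k, k))
    for i in range(k):
        e = np.zeros(k)
        e[i] = h
        gp = optimize.approx_fprime(beta + e, nll, 1e-7)
        gm = optimize.approx_fprime(beta - e, nll, 1e-7)
        H[i] = (gp - gm) / (2 * h)
    covb = np.linalg.inv(0.5 * (H + H.T))
    se = np.sqrt(np.diag(covb))
    zc = stats.norm.ppf(1 - alpha / 2)
    hr = {c: float(np.exp(b)) for c, b in zip(names, beta)}
    ci_low = {c: float(np.exp(b - zc * s)) for c, b, s in zip(names, beta, se)}
    ci_high = {c: float(np.exp(b + zc * s)) for c, b, s in zip(names, beta, se)}
    pvals = {c: float(2 * stats.norm.sf(abs(b / s)))
             for c, b, s in zip(names, beta, se)}
    return CoxResult(
        names=names, hr=hr, ci_low=ci_low, ci_high=ci_high, p=pvals,
        n=len(time), events=int(np.asarray(event).sum()),
        loglik=float(-res.fun),
        prop_p={}, prop_global_p=None,
        dropped=dropped, converged=bool(res.success),
    )


def compare_groups(
    data,
    group=None,
    test: str = "t",
    pooled: bool = True,
    yates: bool = False,
) -> tuple[float, float]:
    """Two-group comparison: returns (statistic, p).

    ``test="t"``: classical two-sample t on values, pooled variance by
    default (Welch via ``pooled=False``).  ``test="chisq"``: Pearson
    chi-square on a 2×2 count table (pass ``data`` as the table), without
    continuity correction unless ``yates=True``.  ``test="median"``: Mood's
    median test on values.
    """
    if test == "chisq":
        table = np.asarray(data, dtype=float)
        if table.shape != (2, 2):
            raise DomainError("chisq expects a 2x2 count table")
        chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
        return float(chi2), float(p)
    values = np.asarray(data, dtype=float)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise DomainError(f"need exactly 2 groups, got {len(levels)}")
    a = values[group == levels[0]]
    b = values[group == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise DomainError("each group needs at least 2 observations")
    if test == "t":
        res = stats.ttest_ind(a, b, equal_var=pooled)
        return float(res.statistic), float(res.pvalue)
    if test == "median":
        res = stats.median_test(a, b, correction=yates)
        return float(res.statistic), float(res.pvalue)
    raise DomainError(f"unknown test {test!r}")


def median_test_exact(a, b) -> tuple[np.ndarray, float]:
    """Mood's median test with an exact (hypergeometric) p for small samples.

    Builds the 2×2 table of counts above/not-above the grand median and
    returns it with Fisher's exact two-sided p.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    grand = np.median(np.concatenate([a, b]))
    table = np.array([
        [(a > grand).sum(), (b > grand).sum()],
        [(a <= grand).sum(), (b <= grand).sum()],
    ])
    _, p = stats.fisher_exact(table)
    return table, float(p)


def survival_report(
    cohort: Cohort,
    score_equation: Optional[dict[str, ScoreEquation]] = None,
    extra_covariates: Sequence[str] = (),
    ties: str = "efron",
) -> dict:
    """Mortality analysis: bivariate comparisons then an adjusted Cox model.

    Per subject the MetSx-BMI score is computed with the sex-matched
    equation; survivors (event 0) and non-survivors (event 1) are compared
    (sex and flags by chi-square, age by t-test, score by median test) and
    an adjusted Cox model with sex, age, score and the listed extra
    covariates (flag fields of the record) is fit.
    """
    score_equation = score_equation or {
        s: builtin_equation(s, "bmi") for s in ("female", "male")
    }
    rows = []
    for r in cohort:
        if r.time is None or r.event is None:
            raise DomainError(f"record {r.id!r} missing survival fields")
        row = {
            "id": r.id,
            "time": r.time,
            "event": r.event,
            "male": 1.0 if r.sex == "male" else 0.0,
            "age": r.age,
            "metsx": evaluate(score_equation[r.sex], r),
        }
        for c in extra_covariates:
            row[c] = float(bool(getattr(r, c)))
        rows.append(row)
    df = pd.DataFrame(rows)
    if df["age"].isna().any():
        raise DomainError("age required for every record")
    ev = df["event"].to_numpy()
    if ev.sum() == 0 or ev.sum() == len(ev):
        raise DomainError(
            "survivor comparison needs both events and censored subjects "
            f"(got {int(ev.sum())} events out of {len(ev)})"
        )

    def _counts(col: str) -> list[list[int]]:
        yes_ns = int(df.loc[ev == 1, col].sum())
        yes_s = int(df.loc[ev == 0, col].sum())
        return [[yes_ns, int((ev == 1).sum()) - yes_ns],
                [yes_s, int((ev == 0).sum()) - yes_s]]

    bivariate: dict = {}
    stat, p = compare_groups(np.array(_counts("male")).T, test="chisq")
    bivariate["sex"] = {"test": "chisq", "statistic": stat, "p": p}
    stat, p = compare_groups(df["age"].to_numpy(), ev, test="t")
    bivariate["age"] = {"test": "t", "statistic": stat, "p": p}
    stat, p = compare_groups(df["metsx"].to_numpy(), ev, test="median")
    bivariate["metsx"] = {"test": "median", "statistic": stat, "p": p}
    for c in extra_covariates:
        stat, p = compare_groups(np.array(_counts(c)).T, test="chisq")
        bivariate[c] = {"test": "chisq", "statistic": stat, "p": p}

    quartiles = {}
    for label, mask in (("non_survivor", ev == 1), ("survivor", ev == 0)):
        vals = df.loc[mask, "metsx"].to_numpy()
        if len(vals):
            q1, q2, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
            quartiles[label] = {"q1": float(q1), "median": float(q2),
                                "q3": float(q3), "n": int(len(vals))}

    covnames = ["male", "age", "metsx", *extra_covariates]
    cox = cox_fit(df["time"], df["event"], df[covnames], ties=ties)
    return {
        "n": int(len(df)),
        "events": int(ev.sum()),
        "bivariate": bivariate,
        "metsx_quartiles": quartiles,
        "cox": cox.as_dict(),
    }
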