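"""Agreement and discrimination statistics for score validation.

Pearson correlation with Fisher-z CI and the strength bins used in the
validation study; Lin's concordance correlation coefficient; two-way
random-effects absolute-agreement single-measure ICC; ROC AUC with DeLong
structural-component variance and the paired DeLong comparison of two
correlated AUCs; and the assembled validation battery (score agreement,
discrimination against each binary criterion, correlation with surrogate
markers).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Cohort, DomainError, InsufficientDataError
from .criteria import CRITERIA, classify
from .markers import MARKER_NAMES, compute_all_markers
from .scores import ScoreEquation, builtin_equation, evaluate

__all__ = [
    "AgreementResult",
    "RocResult",
    "pearson_ci",
    "lin_ccc",
    "icc_a1",
    "auc_delong",
    "delong_compare",
    "validate_scores",
]


@dataclass(frozen=True)
class AgreementResult:
    statistic: str
    estimate: float
    ci_low: float
    ci_high: float
    label: str
    n: int


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    delong_variance: float


def _pearson_label(r: float) -> str:
    a = abs(r)
    if a <= 0.3:
        return "insignificant"
    if a <= 0.5:
        return "weak"
    if a <= 0.7:
        return "moderate"
    if a <= 0.9:
        return "strong"
    return "very strong"


def _ccc_label(c: float) -> str:
    if c < 0.90:
        return "poor"
    if c <= 0.95:
        return "moderate"
    if c <= 0.99:
        return "substantial"
    return "near perfect"


def _icc_label(c: float) -> str:
    if c < 0.5:
        return "poor"
    if c < 0.75:
        return "moderate"
    if c < 0.90:
        return "good"
    return "excellent"


def _paired(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-d arrays of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DomainError("inputs must be finite")
    if len(x) < min_n:
        raise InsufficientDataError(f"need n >= {min_n}, got {len(x)}")
    return x, y


def pearson_ci(x, y, alpha: float = 0.05) -> AgreementResult:
    """Pearson r with Fisher-z confidence interval and strength label."""
    x, y = _paired(x, y, 4)
    if np.std(x) == 0 or np.std(y) == 0:
        raise DomainError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    lo, hi = res.confidence_interval(confidence_level=1 - alpha)
    return AgreementResult("pearson", float(res.statistic), float(lo),
                           float(hi), _pearson_label(res.statistic), len(x))


def lin_ccc(x, y, alpha: float = 0.05) -> AgreementResult:
    """Lin's concordance correlation coefficient with z-transform CI.

    ρ_c = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²), with second moments on the
    biased (1/n) scale as in Lin's definition; the CI uses Lin's variance
    of the z-transformed estimate.
    """
    x, y = _paired(x, y, 4)
    n = len(x)
    mx, my = x.mean(), y.mean()
    sx2, sy2 = x.var(), y.var()
    sxy = ((x - mx) * (y - my)).mean()
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise DomainError("CCC undefined: zero total variance")
    ccc = 2.0 * sxy / denom
    if sx2 == 0 or sy2 == 0:
        raise DomainError("CCC CI undefined for zero-variance input")
    r = sxy / math.sqrt(sx2 * sy2)
    if abs(ccc) >= 1.0 - 1e-15:
        c = math.copysign(1.0, ccc)
        return AgreementResult("ccc", c, c, c, _ccc_label(c), n)
    u = (mx - my) / (sx2 * sy2) ** 0.25
    z = math.atanh(ccc)
    one_m_c2 = 1.0 - ccc ** 2
    se2 = (
        (1 - r ** 2) * ccc ** 2 / (one_m_c2 * r ** 2)
        + 2 * ccc ** 3 * (1 - ccc) * u ** 2 / (r * one_m_c2 ** 2)
        - ccc ** 4 * u ** 4 / (2 * r ** 2 * one_m_c2 ** 2)
    ) / (n - 2)
    zc = stats.norm.ppf(1 - alpha / 2)
    half = zc * math.sqrt(max(se2, 0.0))
    return AgreementResult("ccc", float(ccc), math.tanh(z - half),
                           math.tanh(z + half), _ccc_label(ccc), n)


def icc_a1(x, y, alpha: float = 0.05, variant: str = "a1") -> AgreementResult:
    """Intraclass correlation between two measurement methods.

    Default is the two-way random-effects, absolute-agreement,
    single-measure ICC — the variant whose estimate coincides with Lin's
    CCC on large no-bias data.  ``variant`` accepts ``"a1"`` (absolute
    agreement, default), ``"c1"`` (consistency) or ``"1"`` (one-way).
    Small samples (n < 5) return a (wide) interval rather than raising.
    """
    import pingouin as pg  # deferred: heavy import

    x, y = _paired(x, y, 3)
    n = len(x)
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(n), 2),
        "rater": np.tile(["x", "y"], n),
        "score": np.column_stack([x, y]).reshape(-1),
    })
    table = pg.intraclass_corr(data=df, targets="subject", raters="rater",
                               ratings="score")
    aliases = {"a1": ("ICC2", "ICC(A,1)"), "c1": ("ICC3", "ICC(C,1)"),
               "1": ("ICC1", "ICC(1,1)")}[variant]
    idx = table.set_index("Type")
    key = next(k for k in aliases if k in idx.index)
    row = idx.loc[key]
    ci_col = "CI95%" if "CI95%" in idx.columns else "CI95"
    lo, hi = row[ci_col]
    est = float(row["ICC"])
    return AgreementResult("icc", est, float(lo), float(hi),
                           _icc_label(est), n)


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(score: np.ndarray, label: np.ndarray):
    """AUC and DeLong structural components (V10 per positive, V01 per negative)."""
    pos = score[label == 1]
    neg = score[label == 0]
    m, n = len(pos), len(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n          # per-positive components
    v01 = 1.0 - (tz[m:] - ty) / m    # per-negative components
    return auc, v10, v01


def auc_delong(score, label, alpha: float = 0.05) -> RocResult:
    """ROC AUC (Mann–Whitney, midrank ties) with DeLong variance and CI."""
    score = np.asarray(score, dtype=float)
    label = np.asarray(label).astype(int)
    if set(np.unique(label)) - {0, 1}:
        raise DomainError("labels must be binary 0/1")
    m = int((label == 1).sum())
    n = int((label == 0).sum())
    if m == 0 or n == 0:
        raise DomainError("both classes must be present")
    auc, v10, v01 = _delong_components(score, label)
    var = 0.0
    if m > 1:
        var += v10.var(ddof=1) / m
    if n > 1:
        var += v01.var(ddof=1) / n
    zc = stats.norm.ppf(1 - alpha / 2)
    half = zc * math.sqrt(var)
    return RocResult(auc=float(auc), ci_low=max(0.0, auc - half),
                     ci_high=min(1.0, auc + half), n_pos=m, n_neg=n,
                     delong_variance=float(var))


def delong_compare(score_a, score_b, label) -> tuple[float, float]:
    """Paired DeLong test of AUC_a − AUC_b on the same subjects.

    Returns (z, two-sided p).  Degenerate cases with zero estimated variance
    of the difference and zero AUC difference (e.g. identical or
    rank-equivalent scores) return (0, 1).
    """
    score_a = np.asarray(score_a, dtype=float)
    score_b = np.asarray(score_b, dtype=float)
    label = np.asarray(label).astype(int)
    if not (len(score_a) == len(score_b) == len(label)):
        raise DomainError("scores and labels must have identical length")
    auc_a, v10_a, v01_a = _delong_components(score_a, label)
    auc_b, v10_b, v01_b = _delong_components(score_b, label)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 1e-15:
        return (0.0, 1.0) if abs(diff) < 1e-12 else (math.inf, 0.0)
    z = diff / math.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def validate_scores(
    cohort: Cohort,
    equations_wc: Optional[dict[str, ScoreEquation]] = None,
    equations_bmi: Optional[dict[str, ScoreEquation]] = None,
) -> dict:
    """Assemble the validation battery on a scoreable, classifiable cohort.

    Per sex: ICC and CCC between MetSx-WC and MetSx-BMI; AUC of each score
    against each of the four binary criteria with the pairwise DeLong p;
    Pearson correlations (with CI) of each score with every computable
    surrogate marker.  Failures of individual cells are recorded in-place
    and the rest of the report is still emitted.  The report is
    JSON-serialisable.
    """
    equations_wc = equations_wc or {s: builtin_equation(s, "wc") for s in ("female", "male")}
    equations_bmi = equations_bmi or {s: builtin_equation(s, "bmi") for s in ("female", "male")}
    report: dict = {"agreement": {}, "discrimination": {}, "marker_correlations": {}}
    for sex in ("female", "male"):
        sub = [r for r in cohort if r.sex == sex]
        if not sub:
            continue
        swc, sbmi, labels, marker_cols = [], [], {c: [] for c in CRITERIA}, {}
        rows = []
        for r in sub:
            try:
                a = evaluate(equations_wc[sex], r)
                b = evaluate(equations_bmi[sex], r)
                cls = {c: classify(r, c).mets for c in CRITERIA}
            except DomainError:
                continue
            swc.append(a)
            sbmi.append(b)
            for c in CRITERIA:
                labels[c].append(int(cls[c]))
            mk, _ = compute_all_markers(r)
            rows.append({name: mv.value for name, mv in mk.items()})
        if len(swc) < 4:
            report["agreement"][sex] = {"error": "too few usable records"}
            continue
        swc = np.asarray(swc)
        sbmi = np.asarray(sbmi)
        mkframe = pd.DataFrame(rows)

        agr: dict = {}
        for name, fn in (("icc", icc_a1), ("ccc", lin_ccc)):
            try:
                res = fn(swc, sbmi)
                agr[name] = {"estimate": res.estimate, "ci": [res.ci_low, res.ci_high],
                             "label": res.label, "n": res.n}
            except (DomainError, InsufficientDataError) as exc:
                agr[name] = {"error": str(exc)}
        report["agreement"][sex] = agr

        disc: dict = {}
        for c in CRITERIA:
            lab = np.asarray(labels[c])
            cell: dict = {}
            try:
                ra = auc_delong(swc, lab)
                rb = auc_delong(sbmi, lab)
                _, p = delong_compare(swc, sbmi, lab)
                cell = {
                    "metsx_wc": {"auc": ra.auc, "ci": [ra.ci_low, ra.ci_high]},
                    "metsx_bmi": {"auc": rb.auc, "ci": [rb.ci_low, rb.ci_high]},
                    "delong_p": p,
                    "n_pos": ra.n_pos, "n_neg": ra.n_neg,
                }
            except DomainError as exc:
                cell = {"error": str(exc)}
            disc[c] = cell
        report["discrimination"][sex] = disc

        corr: dict = {}
        for name in MARKER_NAMES:
            if name not in mkframe.columns:
                continue
            vals = mkframe[name].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            cell = {}
            for score_name, score_vals in (("metsx_wc", swc), ("metsx_bmi", sbmi)):
                try:
                    res = pearson_ci(score_vals[ok], vals[ok])
                    cell[score_name] = {"r": res.estimate,
                                        "ci": [res.ci_low, res.ci_high],
                                        "label": res.label}
                except (DomainError, InsufficientDataError) as exc:
                    cell[score_name] = {"error": str(exc)}
            corr[name] = cell
        report["marker_correlations"][sex] = corr
    # guarantee serialisability
    json.dumps(report)
    return report
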