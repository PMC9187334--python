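"""The MetSx continuous severity scores.

A MetSx score is a linear index over the five metabolic-syndrome
components — an adiposity measure (waist circumference or BMI), HDL
cholesterol, log triglycerides, systolic blood pressure and fasting
glucose — in their original clinical units.  The built-in equations are the
published sex-specific scores for Mexican adults;
:func:`reconstruct_equation` rebuilds such an equation from standardized
factor loadings and sample moments (the "inverse transformation" from the
standardized factor model back to clinical units).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import reference
from .core import Cohort, DomainError, Moments, SubjectRecord

__all__ = [
    "ScoreEquation",
    "Loadings",
    "builtin_equation",
    "evaluate",
    "reconstruct_equation",
    "score_cohort",
    "score_frame",
]


@dataclass(frozen=True)
class ScoreEquation:
    """Sex- and adiposity-specific linear severity score in clinical units.

    score = intercept + coef_adiposity·X + coef_hdl·HDL
            + coef_lntri·ln(Tri) + coef_sbp·SBP + coef_glu·Glu

    with X the waist circumference (cm) or BMI (kg/m²) per ``adiposity``.
    """

    name: str
    sex: str
    adiposity: str
    intercept: float
    coef_adiposity: float
    coef_hdl: float
    coef_lntri: float
    coef_sbp: float
    coef_glu: float

    def coefficients(self) -> dict[str, float]:
        return {
            "adiposity": self.coef_adiposity,
            "hdl": self.coef_hdl,
            "ln_tri": self.coef_lntri,
            "sbp": self.coef_sbp,
            "glu": self.coef_glu,
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "sex": self.sex,
                "adiposity": self.adiposity,
                "intercept": self.intercept,
                "coefficients": self.coefficients(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScoreEquation":
        d = json.loads(text)
        c = d["coefficients"]
        return cls(
            name=d["name"],
            sex=d["sex"],
            adiposity=d["adiposity"],
            intercept=d["intercept"],
            coef_adiposity=c["adiposity"],
            coef_hdl=c["hdl"],
            coef_lntri=c["ln_tri"],
            coef_sbp=c["sbp"],
            coef_glu=c["glu"],
        )


@dataclass(frozen=True)
class Loadings:
    """Standardized factor weights of the one-factor MetS model.

    The adiposity marker is fixed at 1.000 (it sets the factor's scale, the
    published convention); the remaining weights are completely standardized
    loadings in (−1, 1).  ``hdln`` weights the *negated* HDL indicator.
    """

    sex: str
    adiposity: str
    marker: float = 1.0
    hdln: float = 0.0
    ln_tri: float = 0.0
    sbp: float = 0.0
    glu: float = 0.0

    def __post_init__(self):
        for name in ("hdln", "ln_tri", "sbp", "glu"):
            v = getattr(self, name)
            if not -1 < v < 1:
                raise DomainError(f"loading {name}={v} outside (-1, 1)")


def builtin_equation(sex: str, adiposity: str) -> ScoreEquation:
    """Return the published MetSx equation for the given sex/adiposity pair."""
    key = (sex, adiposity)
    if key not in reference.PUBLISHED_EQUATIONS:
        raise DomainError(f"no built-in equation for sex={sex!r}, adiposity={adiposity!r}")
    intercept, coef = reference.PUBLISHED_EQUATIONS[key]
    return ScoreEquation(
        name=f"MetSx-{adiposity.upper()} ({sex})",
        sex=sex,
        adiposity=adiposity,
        intercept=intercept,
        coef_adiposity=coef["adiposity"],
        coef_hdl=coef["hdl"],
        coef_lntri=coef["ln_tri"],
        coef_sbp=coef["sbp"],
        coef_glu=coef["glu"],
    )


def builtin_loadings(sex: str, adiposity: str) -> Loadings:
    """Published standardized factor weights for the given pair."""
    key = (sex, adiposity)
    if key not in reference.STANDARDIZED_LOADINGS:
        raise DomainError(f"no built-in loadings for sex={sex!r}, adiposity={adiposity!r}")
    lam = reference.STANDARDIZED_LOADINGS[key]
    return Loadings(sex=sex, adiposity=adiposity, marker=lam["marker"],
                    hdln=lam["hdln"], ln_tri=lam["ln_tri"],
                    sbp=lam["sbp"], glu=lam["glu"])


def evaluate(
    eq: ScoreEquation, record: SubjectRecord, allow_sex_mismatch: bool = False
) -> float:
    """Evaluate a score equation on one subject."""
    if record.sex != eq.sex and not allow_sex_mismatch:
        raise DomainError(
            f"record sex {record.sex!r} does not match equation sex {eq.sex!r}"
        )
    x = record.get(eq.adiposity)
    needed = {eq.adiposity: x, "hdl": record.hdl, "sbp": record.sbp,
              "glu": record.glu, "tri": record.tri}
    missing = [k for k, v in needed.items() if v is None]
    if missing:
        raise DomainError(f"record {record.id!r} missing field(s): {missing}")
    return (
        eq.intercept
        + eq.coef_adiposity * x
        + eq.coef_hdl * record.hdl
        + eq.coef_lntri * math.log(record.tri)
        + eq.coef_sbp * record.sbp
        + eq.coef_glu * record.glu
    )


def reconstruct_equation(loadings: Loadings, moments: Moments) -> ScoreEquation:
    """Re-express the standardized factor score in original clinical units.

    The standardized score is Σᵢ λᵢ·zᵢ over {adiposity, HDLN, lnTri, SBP,
    Glu}.  Substituting zᵢ = (xᵢ − μᵢ)/σᵢ gives slope λᵢ/σᵢ per variable and
    intercept −Σ λᵢ μᵢ/σᵢ.  HDL enters negated (HDLN = −HDL), so its clinical
    slope is −λ_hdln/σ_hdl and its mean contributes with opposite sign;
    triglyceride moments are on the log scale.
    """
    for key in Moments.KEYS:
        if moments.sd[key] <= 0:
            raise DomainError(f"zero or negative SD for {key!r}")
    lam = {
        "adiposity": loadings.marker,
        "hdl": loadings.hdln,
        "ln_tri": loadings.ln_tri,
        "sbp": loadings.sbp,
        "glu": loadings.glu,
    }
    coef = {}
    intercept = 0.0
    for key in ("adiposity", "ln_tri", "sbp", "glu"):
        coef[key] = lam[key] / moments.sd[key]
        intercept -= lam[key] * moments.mean[key] / moments.sd[key]
    # HDLN = -HDL: slope flips sign, mean enters as -mean(HDL)
    coef["hdl"] = -lam["hdl"] / moments.sd["hdl"]
    intercept -= lam["hdl"] * (-moments.mean["hdl"]) / moments.sd["hdl"]
    return ScoreEquation(
        name=f"MetSx-{loadings.adiposity.upper()} ({loadings.sex}, reconstructed)",
        sex=loadings.sex,
        adiposity=loadings.adiposity,
        intercept=intercept,
        coef_adiposity=coef["adiposity"],
        coef_hdl=coef["hdl"],
        coef_lntri=coef["ln_tri"],
        coef_sbp=coef["sbp"],
        coef_glu=coef["glu"],
    )


def score_frame(df: pd.DataFrame, eq: ScoreEquation) -> pd.Series:
    """Vectorised score evaluation on a cohort frame (no sex filtering)."""
    x = df["wc"] if eq.adiposity == "wc" else df["bmi"]
    return (
        eq.intercept
        + eq.coef_adiposity * x.astype(float)
        + eq.coef_hdl * df["hdl"].astype(float)
        + eq.coef_lntri * np.log(df["tri"].astype(float))
        + eq.coef_sbp * df["sbp"].astype(float)
        + eq.coef_glu * df["glu"].astype(float)
    )


def score_cohort(
    cohort: Cohort, equations: dict[str, ScoreEquation]
) -> tuple[pd.DataFrame, dict]:
    """Score every subject with their sex's equation; summarise quartiles.

    ``equations`` maps sex to a :class:`ScoreEquation`.  Records whose sex
    has no equation (or with missing fields) are listed as unscored, not
    fatal.  Returns a per-subject frame (id, sex, metsx) and a summary with
    Q1/median/Q3 per sex and overall.
    """
    rows, unscored = [], []
    for r in cohort:
        eq = equations.get(r.sex)
        if eq is None:
            unscored.append({"id": r.id, "reason": f"no equation for sex {r.sex!r}"})
            continue
        try:
            rows.append({"id": r.id, "sex": r.sex, "metsx": evaluate(eq, r)})
        except DomainError as exc:
            unscored.append({"id": r.id, "reason": str(exc)})
    scored = pd.DataFrame(rows, columns=["id", "sex", "metsx"])

    def _quartiles(values: np.ndarray) -> dict:
        q1, q2, q3 = np.quantile(values, [0.25, 0.5, 0.75])
        return {"q1": float(q1), "median": float(q2), "q3": float(q3),
                "n": int(len(values))}

    summary: dict = {"unscored": unscored}
    if len(scored):
        summary["overall"] = _quartiles(scored["metsx"].to_numpy())
        for sex, grp in scored.groupby("sex"):
            summary[sex] = _quartiles(grp["metsx"].to_numpy())
    return scored, summary
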