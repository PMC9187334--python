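"""Binary metabolic-syndrome diagnosis rule engines.

Implements the four criteria used to validate the continuous MetSx scores:
ATP III, AHA/NHLBI, IDF, and the IDF harmonized definition.  Cut-offs follow
the published texts verbatim: "≥" for WC/glucose/triglyceride/SBP thresholds
and "<" for HDL.  Blood pressure uses systolic pressure only (or a
hypertension diagnosis/treatment flag); no diastolic clause is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import Cohort, DomainError, InsufficientDataError, SubjectRecord

__all__ = ["CRITERIA", "CriteriaResult", "classify", "prevalence"]

CRITERIA = ("ATP3", "AHA_NHLBI", "IDF", "HARMONIZED")

_WC_CUTOFF = {  # cm, (male, female)
    "ATP3": (102.0, 88.0),
    "AHA_NHLBI": (102.0, 88.0),
    "IDF": (90.0, 80.0),
    "HARMONIZED": (90.0, 80.0),
}
_GLU_CUTOFF = {"ATP3": 110.0, "AHA_NHLBI": 100.0, "IDF": 100.0, "HARMONIZED": 100.0}


@dataclass(frozen=True)
class CriteriaResult:
    criterion: str
    component_flags: dict[str, bool]  # keys: wc, glu, tri, bp, hdl
    n_abnormal: int
    mets: bool


def classify(
    record: SubjectRecord, criterion: str, tri_tx_in_harmonized: bool = False
) -> CriteriaResult:
    """Classify one subject under a named MetS criterion.

    Treatment/diagnosis flags are OR-ed into the component rules where the
    published text lists them; absent flags count as false.  For ATP III,
    AHA/NHLBI and the harmonized criteria, MetS = at least 3 of 5 abnormal
    components; for IDF, MetS = abnormal waist plus at least 2 of the other
    4 components.

    ``tri_tx_in_harmonized`` optionally lets lipid-lowering treatment satisfy
    the harmonized triglyceride arm (the published harmonized text lists the
    value-only rule; default follows it).
    """
    if criterion not in CRITERIA:
        raise DomainError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")
    missing = [f for f in ("wc", "glu", "tri", "sbp", "hdl")
               if getattr(record, f) is None]
    if missing:
        raise DomainError(
            f"record {record.id!r}: criterion {criterion} needs field(s) {missing}"
        )
    male = record.sex == "male"
    wc_cut = _WC_CUTOFF[criterion][0 if male else 1]
    hdl_cut = 40.0 if male else 50.0

    wc_flag = record.wc >= wc_cut
    glu_flag = record.glu >= _GLU_CUTOFF[criterion]
    tri_flag = record.tri >= 150.0
    bp_flag = record.sbp >= 130.0 or record.htn_dx
    hdl_flag = record.hdl < hdl_cut

    if criterion == "ATP3":
        glu_flag = glu_flag or record.diabetes_dx
    elif criterion in ("AHA_NHLBI", "IDF"):
        glu_flag = glu_flag or record.diabetes_dx
        tri_flag = tri_flag or record.tri_tx
    elif criterion == "HARMONIZED":
        glu_flag = glu_flag or record.glu_tx
        if tri_tx_in_harmonized:
            tri_flag = tri_flag or record.tri_tx

    flags = {"wc": wc_flag, "glu": glu_flag, "tri": tri_flag,
             "bp": bp_flag, "hdl": hdl_flag}
    n_abnormal = sum(flags.values())
    if criterion == "IDF":
        mets = wc_flag and (n_abnormal - int(wc_flag)) >= 2
    else:
        mets = n_abnormal >= 3
    return CriteriaResult(criterion=criterion, component_flags=flags,
                          n_abnormal=n_abnormal, mets=mets)


def prevalence(cohort: Cohort, criterion: str, by_sex: bool = False) -> dict:
    """MetS prevalence (count and percentage) under one criterion.

    Records missing a mandatory component are skipped and counted as
    unclassifiable; at least one record must be classifiable.
    """
    results: list[tuple[str, bool]] = []
    unclassifiable = 0
    for r in cohort:
        try:
            res = classify(r, criterion)
        except DomainError:
            unclassifiable += 1
            continue
        results.append((r.sex, res.mets))
    if not results:
        raise InsufficientDataError("no classifiable records")

    def _summary(items: list[bool]) -> dict:
        pos = sum(items)
        return {"n": len(items), "positive": pos,
                "percent": 100.0 * pos / len(items)}

    out: dict = {"criterion": criterion, "unclassifiable": unclassifiable}
    out["overall"] = _summary([m for _, m in results])
    if by_sex:
        for sex in ("female", "male"):
            items = [m for s, m in results if s == sex]
            if items:
                out[sex] = _summary(items)
    return out
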