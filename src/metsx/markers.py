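"""Surrogate markers of insulin resistance and obesity.

Closed-form indices computed from fasting biochemistry and anthropometry:
HOMA-IR, QUICKI, SPISE, METS-IR, TG/HDL, TyG, LAP, VAI, METS-VF, VAT, WHtR,
plus BMI itself.  Inputs are in conventional units (glucose, triglycerides
and HDL in mg/dL; insulin in µUI/mL; waist in cm; height in m); LAP and VAI
convert lipids to mmol/L internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import DomainError, SubjectRecord

__all__ = ["MarkerValue", "MARKER_NAMES", "compute_marker", "compute_all_markers"]

#: mg/dL → mmol/L divisors (standard molar masses); overridable for labs
#: that report with slightly different conversion conventions.
TRI_MGDL_PER_MMOL = 88.57
HDL_MGDL_PER_MMOL = 38.67

MARKER_NAMES = (
    "BMI", "HOMA_IR", "QUICKI", "SPISE", "METS_IR", "TG_HDL",
    "TyG", "LAP", "VAI", "METS_VF", "VAT", "WHtR",
)

_REQUIRED_FIELDS = {
    "BMI": ("bmi",),
    "HOMA_IR": ("insulin", "glu"),
    "QUICKI": ("insulin", "glu"),
    "SPISE": ("hdl", "tri", "bmi"),
    "METS_IR": ("glu", "tri", "bmi", "hdl"),
    "TG_HDL": ("tri", "hdl"),
    "TyG": ("tri", "glu"),
    "LAP": ("wc", "tri"),
    "VAI": ("wc", "bmi", "tri", "hdl"),
    "METS_VF": ("glu", "tri", "bmi", "hdl", "wc", "height", "age"),
    "VAT": ("glu", "tri", "bmi", "hdl", "wc", "height", "age"),
    "WHtR": ("wc", "height"),
}


@dataclass(frozen=True)
class MarkerValue:
    name: str
    value: float
    inputs_used: tuple[str, ...]


def _mets_ir(glu: float, tri: float, bmi: float, hdl: float) -> float:
    ln_hdl = math.log(hdl)
    if ln_hdl == 0.0:
        raise DomainError("METS-IR undefined at HDL = 1 mg/dL (ln HDL = 0)")
    return math.log(2.0 * glu + tri) * bmi / ln_hdl


def _whtr(wc: float, height: float) -> float:
    # WC in cm over height in cm: dimensionless, typically 0.4-0.7
    return wc / (100.0 * height)


def _mets_vf(r: SubjectRecord) -> float:
    mets_ir = _mets_ir(r.glu, r.tri, r.bmi, r.hdl)
    if mets_ir <= 0:
        raise DomainError("METS-VF undefined for non-positive METS-IR")
    whtr = _whtr(r.wc, r.height)
    sex_code = 1.0 if r.sex == "male" else 0.0
    return (
        4.466
        + 0.011 * math.log(mets_ir) ** 3
        + 3.239 * math.log(whtr) ** 3
        + 0.319 * sex_code
        + 0.594 * math.log(r.age)
    )


def compute_marker(record: SubjectRecord, name: str) -> MarkerValue:
    """Compute one named surrogate marker for a subject."""
    if name not in _REQUIRED_FIELDS:
        raise DomainError(f"unknown marker {name!r}")
    required = _REQUIRED_FIELDS[name]
    missing = [f for f in required if getattr(record, f) is None]
    if missing:
        raise DomainError(f"marker {name}: missing field(s) {missing}")
    r = record
    tri_mmol = r.tri / TRI_MGDL_PER_MMOL if r.tri is not None else None
    hdl_mmol = r.hdl / HDL_MGDL_PER_MMOL if r.hdl is not None else None

    if name == "BMI":
        value = r.bmi
    elif name == "HOMA_IR":
        value = r.insulin * r.glu / (18.0 * 22.5)
    elif name == "QUICKI":
        denom = math.log(r.insulin) + math.log(r.glu)
        if denom == 0.0:
            raise DomainError("QUICKI undefined: ln(INS) + ln(Glu) = 0")
        value = 1.0 / denom
    elif name == "SPISE":
        value = 600.0 * r.hdl ** 0.185 / (r.tri ** 0.2 * r.bmi ** 1.338)
    elif name == "METS_IR":
        value = _mets_ir(r.glu, r.tri, r.bmi, r.hdl)
    elif name == "TG_HDL":
        value = r.tri / r.hdl
    elif name == "TyG":
        value = math.log(r.tri * r.glu) / 2.0
    elif name == "LAP":
        offset = 58.0 if r.sex == "female" else 65.0
        value = (r.wc - offset) * tri_mmol
    elif name == "VAI":
        if r.sex == "female":
            value = (r.wc / (1.89 * r.bmi + 36.58)) * (tri_mmol / 0.81) * (1.52 / hdl_mmol)
        else:
            value = (r.wc / (1.88 * r.bmi + 39.68)) * (tri_mmol / 1.03) * (1.31 / hdl_mmol)
    elif name == "METS_VF":
        value = _mets_vf(r)
    elif name == "VAT":
        value = math.exp(_mets_vf(r))
    elif name == "WHtR":
        value = _whtr(r.wc, r.height)
    else:  # pragma: no cover
        raise DomainError(name)
    return MarkerValue(name=name, value=float(value), inputs_used=required)


def compute_all_markers(
    record: SubjectRecord,
) -> tuple[dict[str, MarkerValue], list[str]]:
    """Compute every marker whose inputs are available.

    Returns the computed markers and the list of markers omitted because of
    missing inputs (omission is reported, never raised).
    """
    values: dict[str, MarkerValue] = {}
    omitted: list[str] = []
    for name in MARKER_NAMES:
        if any(getattr(record, f) is None for f in _REQUIRED_FIELDS[name]):
            omitted.append(name)
            continue
        values[name] = compute_marker(record, name)
    return values, omitted
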