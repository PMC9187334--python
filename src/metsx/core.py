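"""Domain types, cohort I/O, and derivation-cohort filtering.

All clinical quantities use fixed conventional units: waist circumference in
cm, height in m, weight in kg, BMI in kg/m², blood pressures in mmHg, fasting
glucose / HDL cholesterol / triglycerides in mg/dL, insulin in µUI/mL.
Conversions to molar units happen only inside the surrogate-marker formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DomainError",
    "SchemaError",
    "RowError",
    "InsufficientDataError",
    "SubjectRecord",
    "Cohort",
    "Moments",
    "ExclusionTally",
    "compute_bmi",
    "read_cohort",
    "write_cohort",
    "filter_derivation_cohort",
    "moments_of",
    "MODEL_VARIABLES",
]


class DomainError(ValueError):
    """A clinical value outside its mathematically valid domain."""


class SchemaError(ValueError):
    """Cohort file does not conform to the expected column schema."""


class RowError(ValueError):
    """A specific row of a cohort file could not be parsed."""

    def __init__(self, row_id: str, field_name: str, message: str):
        self.row_id = row_id
        self.field_name = field_name
        super().__init__(f"row {row_id!r}, field {field_name!r}: {message}")


class InsufficientDataError(ValueError):
    """Too few usable records for the requested statistic."""


SEXES = ("female", "male")

#: The five observed indicators of the one-factor MetS model, keyed by the
#: adiposity measure used.  "hdl" is stored on its natural (positive) scale
#: and negated inside the model; "tri" enters on the natural-log scale.
MODEL_VARIABLES = {
    "wc": ("wc", "hdl", "tri", "sbp", "glu"),
    "bmi": ("bmi", "hdl", "tri", "sbp", "glu"),
}

_NUMERIC_FIELDS = (
    "age", "wc", "height", "weight", "bmi", "sbp", "dbp",
    "glu", "hdl", "tri", "insulin", "time",
)
_FLAG_FIELDS = ("pregnant", "diabetes_dx", "htn_dx", "tri_tx", "glu_tx")

#: Canonical column order of the delimited cohort-file schema.
COHORT_COLUMNS = (
    "id", "sex", "age", "wc", "height", "weight", "bmi", "sbp", "dbp",
    "glu", "hdl", "tri", "insulin", "pregnant", "diabetes_dx", "htn_dx",
    "tri_tx", "glu_tx", "time", "event",
)

#: Columns that must exist in a cohort file (cells may still be empty).
MANDATORY_COLUMNS = ("id", "sex", "age", "wc", "sbp", "glu", "hdl", "tri")


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, weight (kg) over height (m) squared."""
    if not (weight > 0 and height > 0):
        raise DomainError(
            f"weight and height must be positive, got {weight}, {height}"
        )
    return weight / height ** 2


@dataclass(frozen=True)
class SubjectRecord:
    """One person's anthropometric, blood-pressure and biochemical fields.

    Optional fields are ``None`` when not measured; diagnosis/treatment
    flags default to False (absence of a recorded diagnosis).
    """

    id: str
    sex: str
    age: Optional[float] = None
    wc: Optional[float] = None
    height: Optional[float] = None
    weight: Optional[float] = None
    bmi: Optional[float] = None
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    glu: Optional[float] = None
    hdl: Optional[float] = None
    tri: Optional[float] = None
    insulin: Optional[float] = None
    pregnant: bool = False
    diabetes_dx: bool = False
    htn_dx: bool = False
    tri_tx: bool = False
    glu_tx: bool = False
    time: Optional[float] = None
    event: Optional[int] = None

    def __post_init__(self):
        if self.sex not in SEXES:
            raise DomainError(f"sex must be one of {SEXES}, got {self.sex!r}")
        for name in _NUMERIC_FIELDS:
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise DomainError(f"{name} must be strictly positive, got {v}")
        if self.bmi is None and self.weight is not None and self.height is not None:
            object.__setattr__(self, "bmi", compute_bmi(self.weight, self.height))
        elif (
            self.bmi is not None
            and self.weight is not None
            and self.height is not None
        ):
            implied = compute_bmi(self.weight, self.height)
            if abs(self.bmi - implied) > 1e-6:
                raise DomainError(
                    f"bmi {self.bmi} inconsistent with weight/height ({implied:.4f})"
                )

    def get(self, field_name: str) -> Optional[float]:
        return getattr(self, field_name)

    def has(self, *field_names: str) -> bool:
        return all(getattr(self, f) is not None for f in field_names)


@dataclass
class Cohort:
    """An ordered collection of subject records with unique ids."""

    records: list[SubjectRecord]
    provenance: str = ""

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DomainError(f"duplicate subject ids: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, predicate) -> "Cohort":
        return Cohort([r for r in self.records if predicate(r)], self.provenance)

    def by_sex(self, sex: str) -> "Cohort":
        return self.subset(lambda r: r.sex == sex)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = {c: getattr(r, c) for c in COHORT_COLUMNS}
            rows.append(d)
        df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "") -> "Cohort":
        records = []
        for _, row in df.iterrows():
            records.append(_record_from_mapping(row.to_dict()))
        return cls(records, provenance)


def _parse_flag(value) -> bool:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("", "nan", "none"):
        return False
    if s in ("1", "true", "t", "yes", "y"):
        return True
    if s in ("0", "false", "f", "no", "n"):
        return False
    raise ValueError(f"unparseable flag value {value!r}")


def _parse_number(value) -> Optional[float]:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    s = str(value).strip()
    if s == "" or s.lower() in ("nan", "none", "na"):
        return None
    return float(s)


def _record_from_mapping(d: Mapping) -> SubjectRecord:
    rid = str(d.get("id"))
    sex_raw = d.get("sex")
    sex = str(sex_raw).strip().lower() if sex_raw is not None else ""
    sex = {"f": "female", "w": "female", "woman": "female",
           "m": "male", "man": "male"}.get(sex, sex)
    kwargs: dict = {"id": rid, "sex": sex}
    for name in _NUMERIC_FIELDS:
        if name in d:
            try:
                kwargs[name] = _parse_number(d[name])
            except ValueError as exc:
                raise RowError(rid, name, str(exc)) from exc
    if "event" in d:
        try:
            ev = _parse_number(d["event"])
        except ValueError as exc:
            raise RowError(rid, "event", str(exc)) from exc
        kwargs["event"] = None if ev is None else int(ev)
    for name in _FLAG_FIELDS:
        if name in d:
            try:
                kwargs[name] = _parse_flag(d[name])
            except ValueError as exc:
                raise RowError(rid, name, str(exc)) from exc
    try:
        return SubjectRecord(**kwargs)
    except DomainError as exc:
        raise RowError(rid, "-", str(exc)) from exc


def read_cohort(
    path,
    delimiter: str = ",",
    column_map: Optional[Mapping[str, str]] = None,
    provenance: Optional[str] = None,
) -> Cohort:
    """Read a delimited cohort file into a :class:`Cohort`.

    ``column_map`` renames file columns to the canonical schema
    (``{"file_column": "canonical_name"}``).  BMI is back-filled from
    weight/height when the column is absent or the cell empty.  Empty cells
    are treated as missing; missing optional fields stay absent.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    records = [_record_from_mapping(row.to_dict()) for _, row in df.iterrows()]
    return Cohort(records, provenance or str(path))


def write_cohort(cohort: Cohort, path, delimiter: str = ",") -> None:
    """Write a cohort as delimited text on the canonical schema."""
    df = cohort.to_frame()
    for c in _FLAG_FIELDS:
        df[c] = df[c].map(lambda b: "1" if b else "0")
    df.to_csv(path, sep=delimiter, index=False)


@dataclass
class ExclusionTally:
    """Counts removed per exclusion rule, in application order."""

    age: int = 0
    completeness: int = 0
    pregnancy: int = 0
    diabetes: int = 0
    glucose: int = 0

    @property
    def total(self) -> int:
        return self.age + self.completeness + self.pregnancy + self.diabetes + self.glucose

    def as_dict(self) -> dict:
        return {
            "age": self.age,
            "completeness": self.completeness,
            "pregnancy": self.pregnancy,
            "diabetes": self.diabetes,
            "glucose": self.glucose,
            "total": self.total,
        }


def filter_derivation_cohort(
    cohort: Cohort, adiposity: str = "wc"
) -> tuple[Cohort, ExclusionTally]:
    """Apply the derivation-cohort inclusion rules.

    Retains adults aged 20–59 with complete model variables, excluding
    pregnant women and subjects with known or suspected diabetes
    (diagnosis flag, or fasting glucose above 125 mg/dL).  Rules are applied
    in order: age, completeness, pregnancy, diabetes diagnosis, glucose.
    """
    if adiposity not in MODEL_VARIABLES:
        raise DomainError(f"adiposity must be 'wc' or 'bmi', got {adiposity!r}")
    needed = MODEL_VARIABLES[adiposity]
    tally = ExclusionTally()
    kept = []
    for r in cohort:
        if r.age is None or not (20 <= r.age <= 59):
            tally.age += 1
            continue
        if not r.has(*needed):
            tally.completeness += 1
            continue
        if r.pregnant:
            tally.pregnancy += 1
            continue
        if r.diabetes_dx:
            tally.diabetes += 1
            continue
        if r.glu > 125:
            tally.glucose += 1
            continue
        kept.append(r)
    return Cohort(kept, cohort.provenance), tally


@dataclass
class Moments:
    """Per-variable mean and sample SD of the model variables for one sex.

    Keys are ``adiposity`` (WC or BMI per :attr:`adiposity`), ``hdl`` (on the
    natural positive scale; the model negates it), ``ln_tri`` (moments taken
    on the log scale), ``sbp`` and ``glu``.  SDs use denominator n−1.
    """

    sex: str
    adiposity: str
    n: int
    mean: dict[str, float]
    sd: dict[str, float]
    zero_sd_vars: list[str] = field(default_factory=list)

    KEYS = ("adiposity", "hdl", "ln_tri", "sbp", "glu")

    def __post_init__(self):
        if self.n < 2:
            raise InsufficientDataError(f"need n >= 2, got {self.n}")
        self.zero_sd_vars = [k for k in self.KEYS if self.sd.get(k, 1.0) == 0.0]


def moments_of(cohort: Cohort, adiposity: str, sex: str) -> Moments:
    """Mean and sample SD of adiposity, HDL, ln(Tri), SBP and Glu for one sex.

    Zero SDs are flagged in ``zero_sd_vars`` rather than raised here; the
    error surfaces where standardization actually divides by them.
    """
    if adiposity not in MODEL_VARIABLES:
        raise DomainError(f"adiposity must be 'wc' or 'bmi', got {adiposity!r}")
    needed = MODEL_VARIABLES[adiposity]
    rows = [r for r in cohort if r.sex == sex and r.has(*needed)]
    if len(rows) < 2:
        raise InsufficientDataError(
            f"need >= 2 complete {sex} records, got {len(rows)}"
        )
    cols = {
        "adiposity": np.array([r.get(needed[0]) for r in rows], dtype=float),
        "hdl": np.array([r.hdl for r in rows], dtype=float),
        "ln_tri": np.log([r.tri for r in rows]),
        "sbp": np.array([r.sbp for r in rows], dtype=float),
        "glu": np.array([r.glu for r in rows], dtype=float),
    }
    mean = {k: float(np.mean(v)) for k, v in cols.items()}
    sd = {k: float(np.std(v, ddof=1)) for k, v in cols.items()}
    return Moments(sex=sex, adiposity=adiposity, n=len(rows), mean=mean, sd=sd)
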