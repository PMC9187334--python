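"""Synthetic cohorts with the single-latent-factor structure of MetS.

Each subject carries a latent severity F ~ N(0, 1); the five transformed
indicators are z_i = λ_i·F + √(1 − λ_i²)·ε_i with independent standard-normal
ε (completely standardized metric), then mapped to clinical units: adiposity,
SBP and glucose by μ + σ·z, HDL by negating the HDLN indicator, and
triglycerides by exp(μ_ln + σ_ln·z) so their clinical-scale distribution is
lognormal.  Defaults emulate the published derivation sample of Mexican
adults (its per-sex means/SDs and standardized loadings); the marker loading
is capped at 0.999 because a generative standardized model cannot carry a
loading of exactly 1 (it would need zero uniqueness).

Insulin — needed only to exercise HOMA-IR/QUICKI — is a lognormal whose
median rises with F; its parameters are conventions of this generator, not
survey estimates.  Survival times for the application stage are exponential
with hazard baseline·exp(β·score) and independent exponential censoring
calibrated to a target censoring fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import reference
from .core import Cohort, DomainError, SubjectRecord
from .scores import ScoreEquation, evaluate

__all__ = ["GeneratorSpec", "generate_cohort", "generate_survival"]

_MARKER_CAP = 0.999


def _default_loadings(sex: str, adiposity: str) -> dict[str, float]:
    lam = dict(reference.STANDARDIZED_LOADINGS[(sex, adiposity)])
    lam["marker"] = min(lam["marker"], _MARKER_CAP)
    return lam


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic-cohort generator.

    ``n`` is the number of subjects per sex.  Loadings and clinical moments
    default to the published derivation-sample values; ``ln_tri_sd`` to the
    package-wide lognormal convention.  Height moments (m) and the insulin
    link (``insulin_ln_median``, ``insulin_slope`` on F, ``insulin_ln_sd``)
    are generator conventions, labelled as such.
    """

    n: dict[str, int] = field(default_factory=lambda: {"female": 1000, "male": 1000})
    loadings_wc: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: _default_loadings(s, "wc") for s in ("female", "male")}
    )
    loadings_bmi: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: _default_loadings(s, "bmi") for s in ("female", "male")}
    )
    moments: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            s: dict(reference.DERIVATION_MOMENTS[s]) for s in ("female", "male")
        }
    )
    ln_tri_sd: float = reference.LN_TRI_SD_DEFAULT
    height_moments: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"female": (1.58, 0.06), "male": (1.70, 0.07)}
    )
    insulin_ln_median: float = math.log(9.0)
    insulin_slope: float = 0.35
    insulin_ln_sd: float = 0.50
    latent_shift: float = 0.0  # shift of mean latent severity, in SD units

    def validate(self) -> None:
        for lamset in (self.loadings_wc, self.loadings_bmi):
            for sex, lam in lamset.items():
                for key, v in lam.items():
                    if not abs(v) < 1:
                        raise DomainError(
                            f"loading {key}={v} for {sex} must satisfy |λ| < 1"
                        )


def generate_cohort(spec: GeneratorSpec, seed: int) -> Cohort:
    """Draw a cohort from the one-factor model.

    Both WC and BMI indicators are generated from the same latent F (with
    their respective loadings and independent uniqueness), so a single
    cohort supports the WC- and BMI-based scores and their agreement
    statistics.  Deterministic for a given (spec, seed).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    records: list[SubjectRecord] = []
    idx = 0
    for sex in ("female", "male"):
        n = spec.n.get(sex, 0)
        if n == 0:
            continue
        mom = spec.moments[sex]
        lam_wc = spec.loadings_wc[sex]
        lam_bmi = spec.loadings_bmi[sex]
        f = rng.standard_normal(n) + spec.latent_shift

        def indicator(lam: float) -> np.ndarray:
            return lam * f + math.sqrt(1.0 - lam ** 2) * rng.standard_normal(n)

        z_wc = indicator(lam_wc["marker"])
        z_bmi = indicator(lam_bmi["marker"])
        # shared (non-adiposity) indicators use the WC-model loadings
        z_hdln = indicator(lam_wc["hdln"])
        z_lntri = indicator(lam_wc["ln_tri"])
        z_sbp = indicator(lam_wc["sbp"])
        z_glu = indicator(lam_wc["glu"])

        wc = mom["wc"][0] + mom["wc"][1] * z_wc
        bmi = mom["bmi"][0] + mom["bmi"][1] * z_bmi
        hdl = -(-mom["hdl"][0] + mom["hdl"][1] * z_hdln)  # HDLN = -HDL
        ln_tri_mu = math.log(mom["tri"][0]) - spec.ln_tri_sd ** 2 / 2.0
        tri = np.exp(ln_tri_mu + spec.ln_tri_sd * z_lntri)
        sbp = mom["sbp"][0] + mom["sbp"][1] * z_sbp
        glu = mom["glu"][0] + mom["glu"][1] * z_glu

        h_mu, h_sd = spec.height_moments[sex]
        height = h_mu + h_sd * rng.standard_normal(n)
        age_mu, age_sd = mom["age"]
        age = np.clip(age_mu + age_sd * rng.standard_normal(n), 20.0, 59.0)
        insulin = np.exp(
            spec.insulin_ln_median
            + spec.insulin_slope * f
            + spec.insulin_ln_sd * rng.standard_normal(n)
        )

        # clip to physiologically positive ranges; the linear-normal map can
        # produce non-positive tails at the published SDs
        wc = np.clip(wc, 40.0, None)
        bmi = np.clip(bmi, 12.0, None)
        hdl = np.clip(hdl, 5.0, None)
        sbp = np.clip(sbp, 30.0, None)  # published SBP SD implies a long left tail
        glu = np.clip(glu, 40.0, None)
        height = np.clip(height, 1.2, None)

        for i in range(n):
            records.append(
                SubjectRecord(
                    id=f"S{idx:06d}",
                    sex=sex,
                    age=float(age[i]),
                    wc=float(wc[i]),
                    height=float(height[i]),
                    weight=float(bmi[i] * height[i] ** 2),
                    bmi=float(bmi[i]),
                    sbp=float(sbp[i]),
                    glu=float(glu[i]),
                    hdl=float(hdl[i]),
                    tri=float(tri[i]),
                    insulin=float(insulin[i]),
                )
            )
            idx += 1
    return Cohort(records, provenance=f"synthetic(seed={seed})")


def generate_survival(
    cohort: Cohort,
    eq: dict[str, ScoreEquation],
    beta: float,
    baseline: float,
    censor_rate: float,
    seed: int,
) -> Cohort:
    """Attach exponential survival times with hazard baseline·exp(β·score).

    Censoring is an independent exponential time whose rate is calibrated
    (by bisection on the expected event fraction) so that the expected
    censored fraction equals ``censor_rate``.
    """
    if baseline <= 0:
        raise DomainError(f"baseline hazard must be positive, got {baseline}")
    if not 0.0 <= censor_rate <= 1.0:
        raise DomainError("censor_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    scores = np.array([evaluate(eq[r.sex], r) for r in cohort])
    hazard = baseline * np.exp(beta * scores)
    t_event = rng.exponential(1.0 / hazard)

    if censor_rate <= 0.0:
        time, event = t_event, np.ones(len(t_event), dtype=int)
    elif censor_rate >= 1.0:
        time = rng.exponential(1.0 / (hazard * 1e6))
        event = np.zeros(len(t_event), dtype=int)
    else:
        # P(censored | h, rate c) = c/(h+c); solve mean over subjects = target
        lo, hi = 1e-12, 1e12
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            frac = float(np.mean(mid / (hazard + mid)))
            if frac < censor_rate:
                lo = mid
            else:
                hi = mid
        c_rate = math.sqrt(lo * hi)
        t_cens = rng.exponential(1.0 / c_rate, size=len(t_event))
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)

    new_records = [
        replace(r, time=float(max(t, 1e-12)), event=int(e))
        for r, t, e in zip(cohort, time, event)
    ]
    return Cohort(new_records, provenance=cohort.provenance + "+survival")
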