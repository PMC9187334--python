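"""One-factor confirmatory factor analysis by maximum likelihood.

The MetS measurement model treats the five transformed components
(adiposity, −HDL, ln Tri, SBP, Glu; all standardized) as indicators of a
single latent severity factor F:

    x_i = λ_i·F + ε_i,   Σ(θ) = φ·λλᵀ + diag(θ)

with the adiposity loading fixed at 1 to set the factor's scale and the
factor variance φ free.  Estimation minimises the normal-theory ML
discrepancy

    F_ML = ln|Σ(θ)| + tr(S·Σ(θ)⁻¹) − ln|S| − p

over an unconstrained reparameterisation (free loadings, log θ, log φ) with
a quasi-Newton optimiser; (n−1)·F_ML is the model χ².  The goodness-of-fit
suite (RMSEA, SRMR, GFI, AGFI, CFI, NFI, AIC) follows the standard SEM
definitions, with the independence (diagonal-covariance) model as the
comparative baseline.  The end-to-end pipeline :func:`derive_scores` runs
filter → transform → correlation matrix → CFA → standardized solution →
inverse transformation to a clinical-unit score equation, per sex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .core import (
    Cohort,
    DomainError,
    InsufficientDataError,
    MODEL_VARIABLES,
    Moments,
    filter_derivation_cohort,
    moments_of,
)
from .scores import Loadings, ScoreEquation, reconstruct_equation

__all__ = [
    "CfaFit",
    "FitIndices",
    "fit_one_factor",
    "fit_baseline",
    "fit_indices",
    "transform_variables",
    "derive_scores",
]

_THETA_FLOOR = 1e-8  # uniqueness below this is reported as a Heywood case


@dataclass
class CfaFit:
    """Maximum-likelihood solution of the one-factor model."""

    loadings: np.ndarray          # unstandardized, marker fixed at 1
    uniquenesses: np.ndarray      # θ_i ≥ 0
    factor_variance: float        # φ
    implied_cov: np.ndarray       # Σ(θ̂)
    sample_cov: np.ndarray        # S
    n: int
    p: int
    q: int                        # free parameters
    f_ml: float
    chi2: float
    df: int
    loglik: float
    converged: bool
    heywood: list[int] = field(default_factory=list)
    marker_index: int = 0

    @property
    def standardized_loadings(self) -> np.ndarray:
        """Completely standardized loadings λ_i√φ / √(λ_i²φ + θ_i)."""
        lam, th, phi = self.loadings, self.uniquenesses, self.factor_variance
        return lam * math.sqrt(phi) / np.sqrt(lam ** 2 * phi + th)


@dataclass
class FitIndices:
    rmsea: Optional[float]
    srmr: float
    gfi: float
    agfi: Optional[float]
    cfi: Optional[float]
    nfi: Optional[float]
    aic: float

    def as_dict(self) -> dict:
        return {"rmsea": self.rmsea, "srmr": self.srmr, "gfi": self.gfi,
                "agfi": self.agfi, "cfi": self.cfi, "nfi": self.nfi,
                "aic": self.aic}


def _check_spd(S: np.ndarray, label: str) -> None:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise DomainError(f"{label} must be a square matrix")
    if not np.allclose(S, S.T, atol=1e-10):
        raise DomainError(f"{label} must be symmetric")
    eigmin = np.linalg.eigvalsh(S).min()
    if eigmin <= 0:
        raise DomainError(f"{label} must be positive definite (min eig {eigmin:.3g})")


def _f_ml(S: np.ndarray, sigma: np.ndarray, logdet_s: float, p: int) -> float:
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    return logdet + float(np.trace(np.linalg.solve(sigma, S))) - logdet_s - p


def _implied(lam: np.ndarray, theta: np.ndarray, phi: float) -> np.ndarray:
    return phi * np.outer(lam, lam) + np.diag(theta)


def _loglik(S: np.ndarray, sigma: np.ndarray, n: int, p: int) -> float:
    """Multivariate-normal log-likelihood of the sample at Σ (means profiled)."""
    sign, logdet = np.linalg.slogdet(sigma)
    tr = float(np.trace(np.linalg.solve(sigma, S)))
    return -0.5 * n * (p * math.log(2 * math.pi) + logdet + tr)


def fit_one_factor(
    S: np.ndarray,
    n: int,
    marker_index: int = 0,
    max_iter: int = 500,
) -> CfaFit:
    """Fit the one-factor model to a covariance matrix by maximum likelihood.

    ``S`` is the sample covariance (a correlation matrix when fitting
    standardized variables); the loading at ``marker_index`` is fixed at 1.
    Uniquenesses and the factor variance are kept positive through a log
    reparameterisation; uniquenesses that collapse to (numerical) zero are
    reported as Heywood cases, not silently clamped.
    """
    S = np.asarray(S, dtype=float)
    _check_spd(S, "sample covariance S")
    p = S.shape[0]
    if n <= p:
        raise DomainError(f"need n > p = {p}, got n = {n}")
    free_idx = [i for i in range(p) if i != marker_index]
    sign, logdet_s = np.linalg.slogdet(S)

    # start values: loadings from covariances with the marker, half-split
    # variance between common factor and uniqueness
    phi0 = max(0.5 * S[marker_index, marker_index], 1e-3)
    lam0 = S[free_idx, marker_index] / phi0 if free_idx else np.array([])
    theta0 = np.maximum(0.5 * np.diag(S), 1e-3)
    x0 = np.concatenate([lam0, np.log(theta0), [math.log(phi0)]])

    def unpack(x):
        lam = np.empty(p)
        lam[marker_index] = 1.0
        lam[free_idx] = x[: p - 1]
        theta = np.exp(x[p - 1: 2 * p - 1])
        phi = math.exp(x[-1])
        return lam, theta, phi

    def objective(x):
        lam, theta, phi = unpack(x)
        return _f_ml(S, _implied(lam, theta, phi), logdet_s, p)

    res = optimize.minimize(
        objective, x0, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-9},
    )
    # polish: a short Nelder-Mead pass guards against a sloppy quasi-Newton
    # stop near a flat ridge (log-θ coordinates can be badly scaled)
    res2 = optimize.minimize(
        objective, res.x, method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-12, "fatol": 1e-14},
    )
    if res2.fun < res.fun:
        res = res2
    lam, theta, phi = unpack(res.x)
    f_val = max(float(res.fun), 0.0)
    sigma = _implied(lam, theta, phi)
    q = (p - 1) + p + 1
    df = p * (p + 1) // 2 - q
    heywood = [i for i in range(p) if theta[i] <= _THETA_FLOOR]
    return CfaFit(
        loadings=lam,
        uniquenesses=theta,
        factor_variance=phi,
        implied_cov=sigma,
        sample_cov=S,
        n=n,
        p=p,
        q=q,
        f_ml=f_val,
        chi2=(n - 1) * f_val,
        df=df,
        loglik=_loglik(S, sigma, n, p),
        converged=bool(res.success or res2.success),
        heywood=heywood,
        marker_index=marker_index,
    )


def fit_baseline(S: np.ndarray, n: int) -> CfaFit:
    """Independence model: free variances, zero covariances (closed form)."""
    S = np.asarray(S, dtype=float)
    _check_spd(S, "sample covariance S")
    p = S.shape[0]
    sigma = np.diag(np.diag(S))
    sign, logdet_s = np.linalg.slogdet(S)
    f_val = max(_f_ml(S, sigma, logdet_s, p), 0.0)
    q = p
    return CfaFit(
        loadings=np.zeros(p),
        uniquenesses=np.diag(S).copy(),
        factor_variance=0.0,
        implied_cov=sigma,
        sample_cov=S,
        n=n, p=p, q=q,
        f_ml=f_val,
        chi2=(n - 1) * f_val,
        df=p * (p + 1) // 2 - q,
        loglik=_loglik(S, sigma, n, p),
        converged=True,
    )


def fit_indices(fit: CfaFit, baseline: Optional[CfaFit] = None) -> FitIndices:
    """Goodness-of-fit suite for a fitted model.

    RMSEA = √(max(χ²−df, 0)/(df·(n−1))); SRMR is the root mean square of
    standardized residuals (correlation metric, diagonal included);
    GFI = 1 − tr[(Σ⁻¹S − I)²]/tr[(Σ⁻¹S)²]; AGFI adjusts GFI for model df;
    CFI and NFI compare against the independence baseline; AIC = −2lnL + 2q.
    RMSEA is undefined (None) at df = 0; CFI/NFI are undefined when the
    baseline itself fits perfectly (χ²_b = 0).
    """
    if baseline is None:
        baseline = fit_baseline(fit.sample_cov, fit.n)
    S, sigma = fit.sample_cov, fit.implied_cov
    n, df = fit.n, fit.df

    rmsea = None
    if df > 0:
        rmsea = math.sqrt(max(fit.chi2 - df, 0.0) / (df * (n - 1)))

    d_s = np.sqrt(np.diag(S))
    resid = (S - sigma) / np.outer(d_s, d_s)
    iu = np.triu_indices(fit.p)
    srmr = math.sqrt(float(np.mean(resid[iu] ** 2)))

    W = np.linalg.solve(sigma, S)
    I = np.eye(fit.p)
    gfi = 1.0 - float(np.trace((W - I) @ (W - I))) / float(np.trace(W @ W))
    agfi = None
    if df > 0:
        agfi = 1.0 - (fit.p * (fit.p + 1) / (2.0 * df)) * (1.0 - gfi)

    cfi = nfi = None
    if baseline.chi2 > 0:
        denom = max(baseline.chi2 - baseline.df, fit.chi2 - df, 0.0)
        cfi = 1.0 - (max(fit.chi2 - df, 0.0) / denom if denom > 0 else 0.0)
        nfi = (baseline.chi2 - fit.chi2) / baseline.chi2

    aic = -2.0 * fit.loglik + 2.0 * fit.q
    return FitIndices(rmsea=rmsea, srmr=srmr, gfi=gfi, agfi=agfi,
                      cfi=cfi, nfi=nfi, aic=aic)


def transform_variables(
    cohort_or_frame, adiposity: str = "wc", sex: Optional[str] = None
) -> tuple[pd.DataFrame, Moments]:
    """Build the transformed, standardized indicator matrix.

    Triglycerides are natural-log-transformed, HDL is negated (HDLN), and
    all five variables are standardized to mean 0 / SD 1 (sample SD, n−1) on
    the analysis sample.  Returns the z-matrix (columns adiposityZ, HDLNZ,
    lnTriZ, SBPZ, GluZ) and the clinical-scale moments needed for the later
    inverse transformation.
    """
    if isinstance(cohort_or_frame, Cohort):
        cohort = cohort_or_frame
    else:
        cohort = Cohort.from_frame(cohort_or_frame)
    if sex is not None:
        cohort = cohort.by_sex(sex)
        moments = moments_of(cohort, adiposity, sex)
    else:
        sexes = {r.sex for r in cohort}
        if len(sexes) != 1:
            raise DomainError("mixed-sex cohort: pass sex= to select one")
        moments = moments_of(cohort, adiposity, next(iter(sexes)))
    needed = MODEL_VARIABLES[adiposity]
    rows = [r for r in cohort if r.has(*needed)]
    raw = {
        "adiposity": np.array([r.get(needed[0]) for r in rows], float),
        "hdln": -np.array([r.hdl for r in rows], float),
        "ln_tri": np.log([r.tri for r in rows]),
        "sbp": np.array([r.sbp for r in rows], float),
        "glu": np.array([r.glu for r in rows], float),
    }
    z = {}
    colnames = {"adiposity": f"{needed[0]}Z", "hdln": "HDLNZ",
                "ln_tri": "lnTriZ", "sbp": "SBPZ", "glu": "GluZ"}
    mkey = {"adiposity": "adiposity", "hdln": "hdl", "ln_tri": "ln_tri",
            "sbp": "sbp", "glu": "glu"}
    for key, vals in raw.items():
        sd = moments.sd[mkey[key]]
        if sd == 0:
            raise DomainError(f"zero variance in column {colnames[key]!r}")
        mu = moments.mean[mkey[key]]
        mu = -mu if key == "hdln" else mu
        z[colnames[key]] = (vals - mu) / sd
    return pd.DataFrame(z), moments


@dataclass
class Derivation:
    """Per-sex output of the end-to-end score-derivation pipeline."""

    sex: str
    adiposity: str
    n: int
    exclusions: dict
    fit: CfaFit
    indices: FitIndices
    loadings: Loadings
    moments: Moments
    equation: ScoreEquation

    def report(self) -> dict:
        lam = self.fit.standardized_loadings
        return {
            "sex": self.sex,
            "adiposity": self.adiposity,
            "n": self.n,
            "exclusions": self.exclusions,
            "converged": self.fit.converged,
            "heywood": self.fit.heywood,
            "chi2": self.fit.chi2,
            "df": self.fit.df,
            "fit_indices": self.indices.as_dict(),
            "standardized_loadings": {
                k: float(v)
                for k, v in zip(("marker", "hdln", "ln_tri", "sbp", "glu"), lam)
            },
            "equation": {
                "intercept": self.equation.intercept,
                **self.equation.coefficients(),
            },
        }


def derive_scores(
    cohort: Cohort,
    adiposity: str = "wc",
    apply_filter: bool = True,
    min_n: int = 100,
) -> dict[str, Derivation]:
    """Derive clinical-unit MetSx equations from a raw cohort, per sex.

    Pipeline per sex: (optional) derivation filter → transform/standardize →
    sample correlation matrix → one-factor ML CFA → completely standardized
    solution (marker reported at 1.000 by the published convention) →
    inverse transformation to an original-units :class:`ScoreEquation`.
    A sex with fewer than ``min_n`` usable records is skipped with a warning
    entry rather than an exception.
    """
    out: dict[str, Derivation] = {}
    for sex in ("female", "male"):
        sub = cohort.by_sex(sex)
        if apply_filter:
            sub, tally = filter_derivation_cohort(sub, adiposity)
            exclusions = tally.as_dict()
        else:
            exclusions = {}
        if len(sub) < min_n:
            continue
        z, moments = transform_variables(sub, adiposity, sex=sex)
        corr = np.corrcoef(z.to_numpy(), rowvar=False)
        fit = fit_one_factor(corr, n=len(sub), marker_index=0)
        std = fit.standardized_loadings
        loadings = Loadings(
            sex=sex, adiposity=adiposity,
            marker=1.0,  # published marker convention
            hdln=float(std[1]), ln_tri=float(std[2]),
            sbp=float(std[3]), glu=float(std[4]),
        )
        eq = reconstruct_equation(loadings, moments)
        out[sex] = Derivation(
            sex=sex, adiposity=adiposity, n=len(sub), exclusions=exclusions,
            fit=fit, indices=fit_indices(fit), loadings=loadings,
            moments=moments, equation=eq,
        )
    if not out:
        raise InsufficientDataError(
            f"no sex reached the minimum of {min_n} usable records"
        )
    return out
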