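# Statistical methods and design decisions

This note records the model, the numerical choices, and the points where a
convention had to be chosen among defensible alternatives.

## 1. The one-factor measurement model

Per sex, five indicators are standardized within the analysis sample:
the adiposity marker (WC or BMI), HDLN = −HDL, lnTri = ln(triglycerides),
SBP, and fasting glucose. The model is

```
z_i = λ_i F + ε_i,   F ~ N(0, φ),   ε_i ~ N(0, θ_i) independent
Σ(λ, θ, φ) = φ λλᵀ + diag(θ)
```

with the adiposity loading fixed at 1 for identification. Estimation
minimizes the ML discrepancy

```
F_ML = ln|Σ| + tr(S Σ⁻¹) − ln|S| − p
```

over the 4 free loadings, 5 uniquenesses and φ (q = 10 parameters;
df = 15 − 10 = 5). χ² = (n−1)·F_ML. Optimization is L-BFGS-B on
(λ_free, log θ, log φ) followed by a Nelder–Mead polish; the log
parameterization keeps variances positive, and a uniqueness at the 1e-8
floor is flagged as a Heywood case rather than silently accepted.
Completely standardized loadings are λ_i√φ/√(λ_i²φ + θ_i).

Because the input is a correlation matrix of the standardized indicators,
the reported loadings follow the publication convention: the marker is
shown as 1.000 and the remaining loadings in the completely standardized
metric.

## 2. Fit indices

- RMSEA = √(max(χ²−df, 0)/(df·(n−1)))
- SRMR: root mean square of residuals of the correlation matrix,
  diagonal included (the diagonal residual is 0 for a correlation input,
  so this choice only matters for covariance input)
- GFI = 1 − tr[(Σ⁻¹S − I)²] / tr[(Σ⁻¹S)²]; AGFI = 1 − (p(p+1)/2df)(1−GFI)
- CFI and NFI against the independence (diagonal) baseline, which has the
  closed form F_b = −ln|R|, df_b = p(p−1)/2
- AIC = −2·lnL + 2q with the multivariate-normal log-likelihood

RMSEA, CFI and NFI are undefined (returned as `None`) for saturated or
degenerate baselines rather than coerced to a number.

## 3. Inverse transformation (score equations)

With loadings λ and clinical moments (μ_i, σ_i):

```
b_i = λ_i/σ_i   (b_hdl = −λ_hdln/σ_hdl, since HDLN = −HDL)
intercept = −Σ λ_i μ_i/σ_i   (with μ_hdln = −μ_hdl)
```

lnTri moments are taken on the log scale. The package convention for the
log-scale moments when only clinical moments are published is
μ_ln = ln(mean) − σ_ln²/2 with σ_ln = 0.36, which reproduces the published
clinical mean exactly and the published SD to within 0.4%.

Reconstruction from printed inputs (loadings at 3 decimals, SDs at 2)
reproduces the published slopes within 1.5e-3 absolute; the seven headline
coefficients agree at the third decimal except the women's BMI marker
slope, where 1/5.93 = 0.16863 rounds to 0.169 against a printed 0.168 —
an input-rounding artifact, reported as 0.169 by `scripts/acceptance.py`
since that is what the stated computation yields.

## 4. Criteria, markers

The four binary definitions (ATP III, AHA/NHLBI, IDF, harmonized) are
implemented with their standard cut-offs; diagnosed-condition and
medication flags OR into the matching component where the definition says
so. SBP alone carries the blood-pressure arm (diastolic pressure is
accepted in the data model but not used by the criteria), matching the
indicator set of the score. HDL uses strict `<` at the cut-off.

The 12 surrogate markers use their literature formulas with mg/dL inputs;
mmol/L conversions use 88.57 (triglycerides) and 38.67 (HDL). Markers
whose inputs are missing are omitted per subject and listed, not imputed.

## 5. Validation statistics

- Pearson r with Fisher-z CIs and conventional strength labels.
- Lin's CCC with 1/n moment estimators and the Lin (1989) z-transform CI.
- ICC(A,1) — two-way random effects, absolute agreement, single measures —
  via pingouin. A1 is the variant that, like CCC, penalizes systematic
  offsets between the two scores.
- AUC with DeLong structural components (midrank-based V10/V01), giving
  both CIs and the paired test for two scores on the same subjects. When
  the component difference variance vanishes (identical rankings) the
  paired test returns z = 0, p = 1 rather than 0/0.

## 6. Survival stage

Cox proportional hazards via lifelines with Efron tie handling (default).
A Breslow option is fit directly on the Breslow partial likelihood (BFGS,
Wald CIs from a finite-difference observed information) because lifelines
implements Efron only. Proportionality is checked per covariate with the
scaled-Schoenfeld rank test; the global p sums the per-covariate
chi-squares and is therefore approximate (components are correlated) —
it is labelled as such in the output. Group comparisons: Pearson
chi-square without continuity correction by default, pooled-variance t,
Mood's median test, and an exact (Fisher) variant of the median test for
small samples.

## 7. Synthetic generator

Subjects carry a latent severity F ~ N(0,1) (optionally mean-shifted);
indicators are z_i = λ_i F + √(1−λ_i²) ε_i in the standardized metric and
are mapped to clinical units with the published per-sex moments.
Triglycerides are lognormal (exact clinical mean preserved); both WC and
BMI indicators are drawn from the same F so one cohort supports both
scores and their agreement statistics. The marker loading is capped at
0.999 — a generative standardized model cannot carry a loading of exactly
1. Height and the insulin link (lognormal median rising with F) are
generator conventions needed only to exercise BMI backfill and the
insulin-based markers; they are not survey estimates. Survival times are
exponential with hazard baseline·exp(β·score) and independent exponential
censoring whose rate is calibrated by bisection to a target expected
censored fraction.

Replicate counts in the test suite (20 recovery replicates at n = 5,000
per sex; 100 Cox coverage replicates at n = 2,000) are sized for a CI run
while keeping binomial acceptance bounds (≥19/20, ≥90/100) meaningful.

## 8. Known limitations

- The CFA engine is single-factor only — the model of interest here — and
  normal-theory ML only (no robust corrections).
- The global proportionality p-value is an upper-level approximation.
- The generator reproduces first/second moments and the one-factor
  correlation structure, not survey design effects, skewness beyond the
  triglyceride lognormality, or missingness patterns.
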