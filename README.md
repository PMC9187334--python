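# metsx

Sex-specific continuous metabolic syndrome severity scores (MetSx) for
adults, with the full derivation and validation toolchain: a one-factor
confirmatory factor analysis (CFA) engine, binary metabolic-syndrome
criteria, insulin-resistance surrogate markers, agreement/discrimination
statistics, a Cox survival application stage, and a synthetic cohort
generator for testing at scale.

## Background

Binary metabolic syndrome (MetS) definitions (ATP III, AHA/NHLBI, IDF,
harmonized) discard severity information. A continuous alternative treats
the five MetS components as indicators of a single latent severity factor:
an adiposity marker (waist circumference or BMI), negated HDL cholesterol
(HDLN, so that higher is worse), log triglycerides (lnTri), systolic blood
pressure, and fasting glucose. Fitting a one-factor CFA on the
within-sex standardized indicators — adiposity loading fixed at 1 to
identify the model — and mapping the solution back to clinical units
("inverse transformation") yields a linear score:

```
MetSx = intercept + b_adip·adiposity + b_hdl·HDL + b_lntri·ln(Tri) + b_sbp·SBP + b_glu·Glu
```

The built-in equations are the published sex-specific MetSx-WC and
MetSx-BMI coefficients derived on Mexican adults aged 20–59 from ENSANUT
2018 (4,021 women, 2,546 men after exclusions). Each slope equals the
indicator's standardized loading divided by its sample SD, so the
equations are fully reproducible from the published loading and moment
tables — `scripts/acceptance.py` performs exactly this reconstruction.

## Worked example

```python
from metsx.core import SubjectRecord
from metsx.scores import builtin_equation, evaluate
from metsx.criteria import classify
from metsx.markers import compute_all_markers

r = SubjectRecord(id="p001", sex="female", age=45, wc=96.0, height=1.58,
                  weight=74.0, sbp=134.0, glu=104.0, hdl=42.0, tri=210.0,
                  insulin=14.0)

evaluate(builtin_equation("female", "wc"), r)    # 2.548  (MetSx-WC)
evaluate(builtin_equation("female", "bmi"), r)   # 2.287  (MetSx-BMI)

res = classify(r, "HARMONIZED")
res.n_abnormal, res.mets                          # 5, True

values, omitted = compute_all_markers(r)
values["HOMA_IR"].value                           # 3.595
values["TyG"].value                               # 4.996
values["SPISE"].value                             # 4.411
```

A score of 0 corresponds roughly to the derivation-sample mean severity;
each unit is one SD of the latent factor, so 2.5 marks a subject far into
the abnormal tail (consistent with all five harmonized components flagged).

## Deriving scores on your own cohort

```python
from metsx.cfa import derive_scores
from metsx.synthetic import GeneratorSpec, generate_cohort

cohort = generate_cohort(GeneratorSpec(), seed=1)     # or core.read_cohort("file.csv")
derivations = derive_scores(cohort, adiposity="wc")   # per-sex CFA + equations
derivations["female"].report()                         # loadings, fit indices, equation
```

`derive_scores` applies the derivation filter (age 20–59, complete
indicators, non-pregnant, no diagnosed diabetes, glucose ≤ 125 mg/dL),
standardizes the five indicators, fits the one-factor model by maximum
likelihood, reports RMSEA/SRMR/GFI/AGFI/CFI/NFI/AIC, and reconstructs the
clinical-unit equation.

## Command line

```bash
metsx simulate --n 1000 --seed 7 --out cohort.csv
metsx score    --input cohort.csv --out scored.csv
metsx classify --input cohort.csv --criterion harmonized
metsx markers  --input cohort.csv
metsx derive   --input cohort.csv --adiposity both
metsx validate --input cohort.csv
metsx simulate --n 500 --seed 7 --with-survival --out surv.csv
metsx survive  --input surv.csv
```

## Layout

- `src/metsx/core.py` — subject/cohort model, IO, derivation filter, moments
- `src/metsx/cfa.py` — one-factor ML CFA, fit indices, end-to-end derivation
- `src/metsx/scores.py` — equations, inverse transformation, cohort scoring
- `src/metsx/criteria.py` — ATP III / AHA-NHLBI / IDF / harmonized rules
- `src/metsx/markers.py` — 12 insulin-resistance/adiposity surrogate indices
- `src/metsx/validation.py` — Pearson, Lin's CCC, ICC(A,1), DeLong AUC tests
- `src/metsx/survival.py` — Cox PH (Efron/Breslow), group comparisons
- `src/metsx/synthetic.py` — latent-factor cohort and survival generator
- `docs/methods.md` — statistical methods and design decisions
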