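"""Published reference values behind the MetSx scores for Mexican adults.

The continuous MetSx severity scores were derived from the 2018 Mexican
National Health and Nutrition Survey (ENSANUT 2018; 4021 women, 2546 men aged
20–59 after exclusions).  This module stores the published descriptive
moments of that derivation sample, the standardized factor loadings of the
one-factor MetS model, and the resulting score equations in original clinical
units.  These constants are inputs to the package (reconstruction checks,
synthetic-cohort defaults), not outputs of it.
"""

from __future__ import annotations

#: Derivation-sample size per sex after exclusions.
DERIVATION_N = {"female": 4021, "male": 2546}

#: Mean and sample SD of the derivation sample, by sex, in clinical units
#: (wc cm, bmi kg/m², sbp/dbp mmHg, glu/hdl/tri mg/dL, insulin µUI/mL,
#: age years).
DERIVATION_MOMENTS = {
    "female": {
        "age": (38.15, 10.77),
        "wc": (93.33, 13.49),
        "bmi": (29.20, 5.93),
        "sbp": (127.84, 37.70),
        "dbp": (90.97, 48.54),
        "glu": (89.03, 11.58),
        "insulin": (13.40, 14.72),
        "tri": (141.29, 52.79),
        "hdl": (46.34, 10.44),
    },
    "male": {
        "age": (37.90, 11.41),
        "wc": (95.21, 14.00),
        "bmi": (27.64, 5.31),
        "sbp": (137.50, 34.89),
        "dbp": (94.99, 48.21),
        "glu": (89.63, 11.64),
        "insulin": (10.44, 11.72),
        "tri": (149.25, 54.29),
        "hdl": (44.52, 11.07),
    },
}

#: SD of ln(triglycerides).  Not published; 0.36 makes the implied lognormal
#: mean/SD of Tri match the published clinical-scale moments closely
#: (e.g. women: mean 141.3, SD ≈ 52.6 vs published 52.79).
LN_TRI_SD_DEFAULT = 0.36

#: Published standardized factorial weights of the one-factor MetS model,
#: keyed by (sex, adiposity).  The adiposity marker is printed as 1.000
#: (it identifies the factor scale); the remaining entries are completely
#: standardized loadings.  Order: marker, HDLN, lnTri, SBP, Glu.
STANDARDIZED_LOADINGS = {
    ("female", "wc"): {"marker": 1.000, "hdln": 0.658, "ln_tri": 0.946,
                       "sbp": 0.229, "glu": 0.691},
    ("male", "wc"): {"marker": 1.000, "hdln": 0.785, "ln_tri": 0.898,
                     "sbp": 0.235, "glu": 0.503},
    ("female", "bmi"): {"marker": 1.000, "hdln": 0.661, "ln_tri": 0.895,
                        "sbp": 0.233, "glu": 0.697},
    ("male", "bmi"): {"marker": 1.000, "hdln": 0.771, "ln_tri": 0.860,
                      "sbp": 0.213, "glu": 0.485},
}

#: Published MetSx equations in original clinical units, keyed by
#: (sex, adiposity): (intercept, {adiposity, hdl, ln_tri, sbp, glu}).
#: The HDL coefficient is negative (higher HDL lowers severity).
PUBLISHED_EQUATIONS = {
    ("female", "wc"): (-21.60, {"adiposity": 0.074, "hdl": -0.063,
                                "ln_tri": 2.365, "sbp": 0.006, "glu": 0.060}),
    ("male", "wc"): (-19.447, {"adiposity": 0.071, "hdl": -0.070,
                               "ln_tri": 2.245, "sbp": 0.006, "glu": 0.042}),
    ("female", "bmi"): (-19.052, {"adiposity": 0.168, "hdl": -0.063,
                                  "ln_tri": 2.237, "sbp": 0.006, "glu": 0.060}),
    ("male", "bmi"): (-17.20, {"adiposity": 0.188, "hdl": -0.069,
                               "ln_tri": 2.150, "sbp": 0.006, "glu": 0.041}),
}
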