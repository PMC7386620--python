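"""Stratification constants for the cell-based CVD/diabetes policy model.

The simulated population (ages 35-94) is partitioned by sex, age decade and,
for the CVD-free pool, six categorical cardiovascular risk factors.  The
resulting no-CVD cell array has shape ``(2, 6, 3, 3, 3, 3, 2, 3)``
(sex, age, SBP, LDL, HDL, smoking, diabetes, BMI); the two prior-CVD pools
(prior CHD, prior stroke) are stratified by sex and age only.
"""

from __future__ import annotations

SEXES = ("men", "women")
AGE_GROUPS = ("35-44", "45-54", "55-64", "65-74", "75-84", "85-94")
#: representative age used in the linear predictors, centered at 40
AGE_MIDPOINTS = (40.0, 50.0, 60.0, 70.0, 80.0, 90.0)

SBP_CATEGORIES = ("<130", "130-139.9", ">=140")        # mmHg
LDL_CATEGORIES = ("<100", "100-129.9", ">=130")        # mg/dl
HDL_CATEGORIES = ("<40", "40-59.9", ">=60")            # mg/dl
SMOKING_CATEGORIES = ("none", "secondhand", "active")
DIABETES_CATEGORIES = ("no", "yes")
BMI_CATEGORIES = ("<25", "25-29.9", ">=30")            # kg/m^2

#: factor name -> categories, in cell-array axis order (axes 2..7)
RISK_FACTORS = {
    "sbp": SBP_CATEGORIES,
    "ldl": LDL_CATEGORIES,
    "hdl": HDL_CATEGORIES,
    "smoking": SMOKING_CATEGORIES,
    "diabetes": DIABETES_CATEGORIES,
    "bmi": BMI_CATEGORIES,
}
N_RISK_COMBINATIONS = 486  # 3*3*3*3*2*3

#: category bounds used to validate representative continuous values and to
#: re-derive display labels after an intervention shift
SBP_CATEGORY_BOUNDS = ((80.0, 130.0), (130.0, 140.0), (140.0, 250.0))
BMI_CATEGORY_BOUNDS = ((12.0, 25.0), (25.0, 30.0), (30.0, 60.0))

#: physiologic clamping bounds for shifted continuous values
SBP_PHYSIOLOGIC = (80.0, 250.0)
BMI_PHYSIOLOGIC = (12.0, 60.0)

#: outcomes of the no-CVD risk functions (full risk-factor linear predictor)
NO_CVD_OUTCOMES = (
    "incident_chd",
    "incident_stroke",
    "incident_diabetes",
    "non_cvd_death",
)
#: outcomes of the prior-CVD pools (sex/age linear predictor only)
POST_CVD_OUTCOMES = (
    "post_chd_event",
    "post_chd_cvd_death",
    "post_chd_non_cvd_death",
    "post_stroke_event",
    "post_stroke_cvd_death",
    "post_stroke_non_cvd_death",
)
ALL_OUTCOMES = NO_CVD_OUTCOMES + POST_CVD_OUTCOMES

#: outcomes reported in the ledger / comparison tables
REPORTED_OUTCOMES = (
    "diabetes",
    "mi",
    "stroke",
    "cvd_deaths",
    "non_cvd_deaths",
    "total_deaths",
)
#: outcomes shown in prevented-case tables
TABLE_OUTCOMES = ("diabetes", "mi", "stroke", "cvd_deaths", "total_deaths")

#: fraction of each decade cell promoted to the next decade every cycle
#: (uniform age distribution within a 10-year decade)
AGING_FRACTION = 0.1

SERVING_ML = 355.0  # one 12-oz serving, the size of a soda can in Argentina

DEFAULT_START_YEAR = 2015
DEFAULT_HORIZON_YEARS = 10
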