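"""Default configuration and YAML config handling.

A single structured mapping drives every stage: demography, categorical
risk-factor marginals, SSB consumption profiles, intervention effect sizes
and logistic risk-function coefficients.  ``default_config`` returns the
package's synthetic Argentina-like defaults; ``load_config`` reads and
validates a user YAML file with the same schema (partial files are merged
over the defaults).

Schema (top-level keys)
-----------------------
demography:
    base_counts: {men: [6 floats], women: [6 floats]}  persons per age decade
    entrants:    {men: float, women: float}            new 35-year-olds/year
    start_year, horizon_years
    prior_chd_prevalence / prior_stroke_prevalence: {sex: [6 fractions]}
risk_factors:
    marginals: {factor: {sex: [[p per category] x 6 age groups]}}
    representative: {sbp: [3 mmHg], bmi: [3 kg/m^2]}   per-category values
    heights: {sex: [6 m]}
consumption:
    serving_ml
    low / high: {anchor_servings: float, scaling: {sex: [6 floats]}}
effects:
    sbp_direct: {sex: {mean, ci: [lo, hi]}}            mmHg per serving/day
    rr_diabetes_per_serving: {mean, ci}
    sbp_per_bmi_unit: {sex: {mean, ci}}                mmHg per kg/m^2
    rr_diabetes_per_bmi_unit: {mean, ci, anchor_age_group, log_slope_per_decade}
    kcal_per_serving, kcal_per_pound, pound_kg
coefficients:
    {outcome: {term: {value, ci} | [3 x {value, ci}]}} log-odds scale
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .constants import (
    AGE_GROUPS,
    ALL_OUTCOMES,
    DEFAULT_HORIZON_YEARS,
    DEFAULT_START_YEAR,
    NO_CVD_OUTCOMES,
    RISK_FACTORS,
    SERVING_ML,
    SEXES,
)
from .errors import ConfigurationError, ValidationError

#: terms of the no-CVD logistic risk functions (reference: women, age 40,
#: SBP 120 mmHg, BMI 25 kg/m^2, first category of each factor, no diabetes)
NO_CVD_TERMS = (
    "intercept",
    "male",
    "age_per_year",
    "sbp_per_mmhg",
    "bmi_per_unit",
    "ldl",
    "hdl",
    "smoking",
    "diabetes",
)
POST_CVD_TERMS = ("intercept", "male", "age_per_year")
CATEGORICAL_TERMS = ("ldl", "hdl", "smoking")


def _par(value: float, half: float | None = None) -> dict:
    """Scalar coefficient with a symmetric 95% CI (synthetic default width)."""
    if half is None:
        half = 0.10 * abs(value)
    return {"value": value, "ci": [value - half, value + half]}


def _cat(values: tuple[float, float, float]) -> list[dict]:
    # reference category gets a degenerate CI and is never Monte Carlo varied
    return [
        {"value": v, "ci": [v, v]} if v == 0.0 else _par(v)
        for v in values
    ]


def _default_coefficients() -> dict:
    """Synthetic logistic coefficients for the model risk functions.

    Chosen to give plausible Argentine-scale annual probabilities: incident
    CHD roughly 0.2-3% rising with age, stroke lower, incident diabetes
    around 0.5-1%, and a Gompertz-like age trend in non-CVD death.
    """
    c: dict[str, dict] = {
        "incident_chd": {
            "intercept": _par(-7.90, 0.08),
            "male": _par(0.45),
            "age_per_year": _par(0.055),
            "sbp_per_mmhg": _par(0.015),
            "bmi_per_unit": _par(0.020),
            "ldl": _cat((0.0, 0.25, 0.50)),
            "hdl": _cat((0.0, -0.20, -0.35)),
            "smoking": _cat((0.0, 0.15, 0.45)),
            "diabetes": _par(0.65),
        },
        "incident_stroke": {
            "intercept": _par(-7.44, 0.08),
            "male": _par(0.30),
            "age_per_year": _par(0.062),
            "sbp_per_mmhg": _par(0.020),
            "bmi_per_unit": _par(0.010),
            "ldl": _cat((0.0, 0.10, 0.20)),
            "hdl": _cat((0.0, -0.10, -0.15)),
            "smoking": _cat((0.0, 0.10, 0.35)),
            "diabetes": _par(0.50),
        },
        "incident_diabetes": {
            "intercept": _par(-5.70, 0.08),
            "male": _par(0.10),
            "age_per_year": _par(0.012),
            "sbp_per_mmhg": _par(0.005),
            "bmi_per_unit": _par(0.085),
            "ldl": _cat((0.0, 0.0, 0.0)),
            "hdl": _cat((0.0, -0.05, -0.10)),
            "smoking": _cat((0.0, 0.05, 0.15)),
            "diabetes": {"value": 0.0, "ci": [0.0, 0.0]},
        },
        "non_cvd_death": {
            "intercept": _par(-6.70, 0.08),
            "male": _par(0.30),
            "age_per_year": _par(0.085),
            "sbp_per_mmhg": _par(0.004),
            "bmi_per_unit": _par(0.010),
            "ldl": _cat((0.0, 0.0, 0.0)),
            "hdl": _cat((0.0, 0.0, 0.0)),
            "smoking": _cat((0.0, 0.10, 0.50)),
            "diabetes": _par(0.40),
        },
    }
    post = {
        "post_chd_event": (-4.15, 0.20, 0.020),
        "post_chd_cvd_death": (-3.93, 0.20, 0.050),
        "post_chd_non_cvd_death": (-4.5, 0.20, 0.070),
        "post_stroke_event": (-4.10, 0.10, 0.020),
        "post_stroke_cvd_death": (-3.83, 0.10, 0.055),
        "post_stroke_non_cvd_death": (-4.4, 0.20, 0.070),
    }
    for name, (b0, male, age) in post.items():
        c[name] = {
            "intercept": _par(b0, 0.08),
            "male": _par(male),
            "age_per_year": _par(age),
        }
    return c


def default_config() -> dict:
    """Full synthetic default configuration (plain Python containers)."""
    cfg: dict[str, Any] = {
        "demography": {
            "base_counts": {
                "men": [2350e3, 1900e3, 1500e3, 1050e3, 550e3, 130e3],
                "women": [2300e3, 1950e3, 1600e3, 1250e3, 750e3, 220e3],
            },
            "entrants": {"men": 330e3, "women": 325e3},
            "start_year": DEFAULT_START_YEAR,
            "horizon_years": DEFAULT_HORIZON_YEARS,
            "prior_chd_prevalence": {
                "men": [0.010, 0.025, 0.050, 0.080, 0.110, 0.130],
                "women": [0.0075, 0.019, 0.0375, 0.060, 0.0825, 0.0975],
            },
            "prior_stroke_prevalence": {
                "men": [0.005, 0.012, 0.025, 0.045, 0.070, 0.090],
                "women": [0.004, 0.010, 0.021, 0.038, 0.060, 0.076],
            },
        },
        "risk_factors": {
            "marginals": {
                "sbp": {
                    "men": [
                        [0.62, 0.22, 0.16], [0.52, 0.24, 0.24],
                        [0.42, 0.26, 0.32], [0.34, 0.26, 0.40],
                        [0.28, 0.26, 0.46], [0.24, 0.26, 0.50],
                    ],
                    "women": [
                        [0.72, 0.16, 0.12], [0.60, 0.21, 0.19],
                        [0.46, 0.25, 0.29], [0.36, 0.26, 0.38],
                        [0.28, 0.26, 0.46], [0.24, 0.26, 0.50],
                    ],
                },
                "ldl": {
                    sex: [
                        [0.50, 0.33, 0.17], [0.44, 0.35, 0.21],
                        [0.40, 0.36, 0.24], [0.40, 0.36, 0.24],
                        [0.44, 0.35, 0.21], [0.48, 0.34, 0.18],
                    ]
                    for sex in SEXES
                },
                "hdl": {
                    "men": [[0.30, 0.52, 0.18]] * 6,
                    "women": [[0.18, 0.52, 0.30]] * 6,
                },
                "smoking": {
                    "men": [
                        [0.50, 0.20, 0.30], [0.52, 0.20, 0.28],
                        [0.56, 0.20, 0.24], [0.64, 0.18, 0.18],
                        [0.74, 0.14, 0.12], [0.82, 0.10, 0.08],
                    ],
                    "women": [
                        [0.58, 0.20, 0.22], [0.60, 0.20, 0.20],
                        [0.64, 0.19, 0.17], [0.70, 0.17, 0.13],
                        [0.78, 0.13, 0.09], [0.84, 0.10, 0.06],
                    ],
                },
                "diabetes": {
                    # probability of [no, yes]
                    "men": [[1 - p, p] for p in (0.05, 0.08, 0.12, 0.16, 0.18, 0.18)],
                    "women": [[1 - p, p] for p in (0.04, 0.07, 0.11, 0.15, 0.17, 0.17)],
                },
                "bmi": {
                    "men": [
                        [0.38, 0.42, 0.20], [0.32, 0.44, 0.24],
                        [0.30, 0.44, 0.26], [0.32, 0.43, 0.25],
                        [0.36, 0.42, 0.22], [0.42, 0.40, 0.18],
                    ],
                    "women": [
                        [0.48, 0.32, 0.20], [0.40, 0.35, 0.25],
                        [0.34, 0.37, 0.29], [0.33, 0.38, 0.29],
                        [0.38, 0.37, 0.25], [0.44, 0.36, 0.20],
                    ],
                },
            },
            # category midpoints; open-ended categories get conventional values
            "representative": {"sbp": [120.0, 135.0, 150.0], "bmi": [23.0, 27.5, 33.0]},
            "heights": {
                "men": [1.74, 1.73, 1.72, 1.71, 1.70, 1.69],
                "women": [1.61, 1.60, 1.59, 1.58, 1.57, 1.56],
            },
        },
        "consumption": {
            "serving_ml": SERVING_ML,
            # illustrative self-report-style profile (the survey's per-stratum
            # values are not published); anchored at women 35-44
            "low": {
                "anchor_servings": 0.45,
                "scaling": {
                    "men": [1.30, 0.95, 0.70, 0.50, 0.50, 0.50],
                    "women": [1.00, 0.75, 0.55, 0.40, 0.40, 0.40],
                },
            },
            # sales-scaled estimate: 269.6 ml/day for women 35-44 = 269.6/355
            "high": {
                "anchor_servings": 269.6 / SERVING_ML,
                "scaling": {
                    "men": [1.30, 0.95, 0.70, 0.50, 0.50, 0.50],
                    "women": [1.00, 0.75, 0.55, 0.40, 0.40, 0.40],
                },
            },
        },
        "effects": {
            "sbp_direct": {
                "men": {"mean": 0.78, "ci": [0.09, 1.47]},
                "women": {"mean": 0.61, "ci": [0.27, 1.48]},
            },
            "rr_diabetes_per_serving": {"mean": 1.19, "ci": [1.09, 1.31]},
            "sbp_per_bmi_unit": {
                "men": {"mean": 1.43, "ci": [1.23, 1.64]},
                "women": {"mean": 1.24, "ci": [1.09, 1.39]},
            },
            "rr_diabetes_per_bmi_unit": {
                "mean": 1.17,
                "ci": [0.97, 1.43],
                "anchor_age_group": "55-64",
                # RR declines with age on the log scale
                "log_slope_per_decade": -0.04,
            },
            "kcal_per_serving": 150.0,
            "kcal_per_pound": 3500.0,
            "pound_kg": 0.45359237,
        },
        "coefficients": _default_coefficients(),
    }
    return cfg


def _merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config, merge over defaults, and validate."""
    cfg = default_config()
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, Mapping):
            raise ConfigurationError(f"config file {path} is not a mapping")
        cfg = _merge(cfg, user)
    validate_config(cfg)
    return cfg


def save_config(cfg: Mapping, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=False)


def validate_config(cfg: Mapping) -> None:
    """Check structural completeness and the documented invariants."""
    for section in ("demography", "risk_factors", "consumption", "effects",
                    "coefficients"):
        if section not in cfg:
            raise ConfigurationError(f"missing config section '{section}'")

    demo = cfg["demography"]
    for key in ("base_counts", "entrants"):
        for sex in SEXES:
            if sex not in demo[key]:
                raise ConfigurationError(
                    f"demography.{key} missing stratum '{sex}'")
    for sex in SEXES:
        counts = np.asarray(demo["base_counts"][sex], dtype=float)
        if counts.shape != (len(AGE_GROUPS),):
            raise ConfigurationError(
                f"demography.base_counts.{sex} must list all "
                f"{len(AGE_GROUPS)} age groups {AGE_GROUPS}")
        if (counts < 0).any():
            raise ValidationError(f"negative population count for {sex}")
        for key in ("prior_chd_prevalence", "prior_stroke_prevalence"):
            prev = np.asarray(demo[key][sex], dtype=float)
            if ((prev < 0) | (prev > 1)).any():
                raise ValidationError(f"{key}.{sex} outside [0, 1]")
    if int(demo["horizon_years"]) < 1:
        raise ValidationError("horizon_years must be >= 1")

    rf = cfg["risk_factors"]
    for factor, cats in RISK_FACTORS.items():
        if factor not in rf["marginals"]:
            raise ConfigurationError(f"marginals missing factor '{factor}'")
        for sex in SEXES:
            if sex not in rf["marginals"][factor]:
                raise ConfigurationError(
                    f"marginals.{factor} missing stratum '{sex}'")
            arr = np.asarray(rf["marginals"][factor][sex], dtype=float)
            if arr.shape != (len(AGE_GROUPS), len(cats)):
                raise ConfigurationError(
                    f"marginals.{factor}.{sex} must be "
                    f"{len(AGE_GROUPS)}x{len(cats)}")
            if ((arr < 0) | (arr > 1)).any():
                raise ValidationError(
                    f"marginals.{factor}.{sex} has probabilities outside [0,1]")
            bad = np.abs(arr.sum(axis=1) - 1.0) > 1e-6
            if bad.any():
                group = AGE_GROUPS[int(np.argmax(bad))]
                raise ValidationError(
                    f"marginal for {factor}, {sex}, {group} does not sum to 1")
    for sex in SEXES:
        heights = np.asarray(rf["heights"][sex], dtype=float)
        if ((heights <= 1.2) | (heights >= 2.2)).any():
            raise ValidationError(f"heights.{sex} outside (1.2, 2.2) m")

    cons = cfg["consumption"]
    for label in ("low", "high"):
        prof = cons[label]
        if prof["anchor_servings"] < 0:
            raise ValidationError(f"consumption.{label} anchor is negative")
        for sex in SEXES:
            scaling = np.asarray(prof["scaling"][sex], dtype=float)
            if (scaling < 0).any():
                raise ValidationError(
                    f"consumption.{label}.scaling.{sex} has negative entries")

    eff = cfg["effects"]
    for block in (eff["sbp_direct"]["men"], eff["sbp_direct"]["women"],
                  eff["rr_diabetes_per_serving"],
                  eff["sbp_per_bmi_unit"]["men"], eff["sbp_per_bmi_unit"]["women"],
                  eff["rr_diabetes_per_bmi_unit"]):
        lo, hi = block["ci"]
        if not (lo <= block["mean"] <= hi):
            raise ValidationError(
                f"effect CI {block['ci']} does not contain mean {block['mean']}")
    for const in ("kcal_per_serving", "kcal_per_pound", "pound_kg"):
        if eff[const] <= 0:
            raise ValidationError(f"effects.{const} must be positive")

    coefs = cfg["coefficients"]
    for outcome in ALL_OUTCOMES:
        if outcome not in coefs:
            raise ConfigurationError(f"coefficients missing outcome '{outcome}'")
        terms = NO_CVD_TERMS if outcome in NO_CVD_OUTCOMES else POST_CVD_TERMS
        for term in terms:
            if term not in coefs[outcome]:
                raise ConfigurationError(
                    f"coefficients.{outcome} missing term '{term}'")
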