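"""Synthetic model inputs: demography, risk-factor marginals, consumption.

This module generates, from the structured configuration, every input the
state-transition engine needs: a demographic projection (persons by sex and
age decade plus annual 35-year-old entrants), categorical risk-factor
marginal distributions with representative continuous values, daily SSB
consumption profiles ("low" and "high" estimates, in 12-oz servings), and
logistic risk-function coefficients with 95% CIs for the probabilistic
sensitivity analysis.

Everything is deterministic given its inputs; the ``seed`` arguments are
accepted for interface stability (the default generators draw nothing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .constants import (
    AGE_GROUPS,
    AGING_FRACTION,
    ALL_OUTCOMES,
    BMI_CATEGORY_BOUNDS,
    NO_CVD_OUTCOMES,
    RISK_FACTORS,
    SBP_CATEGORY_BOUNDS,
    SERVING_ML,
    SEXES,
)
from .config import CATEGORICAL_TERMS, NO_CVD_TERMS, POST_CVD_TERMS
from .errors import ConfigurationError, ValidationError

_N_AGE = len(AGE_GROUPS)


# ---------------------------------------------------------------------------
# demography


@dataclass(frozen=True)
class DemographyTable:
    """Projected persons by sex and age decade, with annual 35-y entrants.

    ``base_counts`` is the year-0 population, shape (2 sexes, 6 decades);
    ``entrants`` has shape (horizon, 2): persons entering at age 35 in each
    simulated year.  ``frame`` is the tidy projection (inflow/aging
    bookkeeping only — no mortality), one row per year x sex x age group.
    """

    base_counts: np.ndarray
    entrants: np.ndarray
    start_year: int
    frame: pd.DataFrame = field(repr=False)

    @property
    def horizon_years(self) -> int:
        return self.entrants.shape[0]

    def entrants_for(self, year_index: int) -> np.ndarray:
        return self.entrants[year_index]


def generate_demography(
    base_population_by_stratum: Mapping[str, object],
    annual_entrants: Mapping[str, float],
    horizon_years: int,
    seed: int | None = None,
    start_year: int = 2015,
) -> DemographyTable:
    """Build the demographic projection table.

    The projection applies only cohort bookkeeping: each year one tenth of
    every decade cell is promoted to the next decade, one tenth of the
    oldest decade exits at age 95, and the configured entrants join the
    35-44 group.  Mortality belongs to the simulation engine, not here.
    """
    if horizon_years < 1:
        raise ValidationError("horizon_years must be >= 1")
    counts = np.zeros((2, _N_AGE))
    ent = np.zeros(2)
    for s, sex in enumerate(SEXES):
        if sex not in base_population_by_stratum:
            raise ConfigurationError(f"base population missing stratum '{sex}'")
        row = np.asarray(base_population_by_stratum[sex], dtype=float)
        if row.shape != (_N_AGE,):
            raise ConfigurationError(
                f"base population for '{sex}' must cover all age groups "
                f"{AGE_GROUPS}")
        if (row < 0).any():
            raise ValidationError(f"negative base count for '{sex}'")
        counts[s] = row
        if sex not in annual_entrants:
            raise ConfigurationError(f"entrants missing stratum '{sex}'")
        ent[s] = float(annual_entrants[sex])
    if (ent < 0).any():
        raise ValidationError("entrants must be nonnegative")

    entrants = np.tile(ent, (horizon_years, 1))
    rows = []
    current = counts.copy()
    for t in range(horizon_years + 1):
        for s, sex in enumerate(SEXES):
            for a, group in enumerate(AGE_GROUPS):
                rows.append({
                    "year": start_year + t,
                    "sex": sex,
                    "age_group": group,
                    "count": current[s, a],
                    "entrants_35": ent[s] if (a == 0 and t < horizon_years) else 0.0,
                })
        if t < horizon_years:
            aged = (1 - AGING_FRACTION) * current
            aged[:, 1:] += AGING_FRACTION * current[:, :-1]
            aged[:, 0] += ent
            current = aged
    frame = pd.DataFrame(rows)
    return DemographyTable(base_counts=counts, entrants=entrants,
                           start_year=start_year, frame=frame)


# ---------------------------------------------------------------------------
# risk-factor marginals


@dataclass(frozen=True)
class RiskFactorMarginals:
    """Categorical marginals per sex x age plus representative values.

    ``probs`` maps factor name to an array of shape (2, 6, n_categories).
    The joint cell distribution is the product of the marginals
    (independence across factors within sex x age).
    """

    probs: dict[str, np.ndarray]
    sbp_representative: np.ndarray  # (3,) mmHg
    bmi_representative: np.ndarray  # (3,) kg/m^2
    heights: np.ndarray             # (2, 6) m

    def joint(self, sex_index: int, age_index: int) -> np.ndarray:
        """Joint occupancy over the 486 risk-factor combinations."""
        out = np.ones(())
        for factor in RISK_FACTORS:
            p = self.probs[factor][sex_index, age_index]
            out = np.multiply.outer(out, p)
        return out

    def joint_all(self) -> np.ndarray:
        """Joint occupancies, shape (2, 6, 3, 3, 3, 3, 2, 3)."""
        out = np.empty((2, _N_AGE) + tuple(len(c) for c in RISK_FACTORS.values()))
        for s in range(2):
            for a in range(_N_AGE):
                out[s, a] = self.joint(s, a)
        return out


def generate_risk_factor_marginals(
    profile_config: Mapping, seed: int | None = None
) -> RiskFactorMarginals:
    """Assemble and validate marginals from the ``risk_factors`` config."""
    marg = profile_config["marginals"]
    probs: dict[str, np.ndarray] = {}
    for factor, cats in RISK_FACTORS.items():
        arr = np.empty((2, _N_AGE, len(cats)))
        for s, sex in enumerate(SEXES):
            rows = np.asarray(marg[factor][sex], dtype=float)
            if rows.shape != (_N_AGE, len(cats)):
                raise ConfigurationError(
                    f"marginals for {factor}/{sex} must be "
                    f"{_N_AGE}x{len(cats)}")
            if ((rows < 0) | (rows > 1)).any():
                raise ValidationError(
                    f"marginals for {factor}/{sex} outside [0, 1]")
            bad = np.abs(rows.sum(axis=1) - 1.0) > 1e-6
            if bad.any():
                raise ValidationError(
                    f"marginal for {factor}/{sex}/"
                    f"{AGE_GROUPS[int(np.argmax(bad))]} does not sum to 1")
            # renormalize residual float error so sums hold to 1e-9 exactly
            arr[s] = rows / rows.sum(axis=1, keepdims=True)
        probs[factor] = arr

    rep = profile_config["representative"]
    sbp_rep = np.asarray(rep["sbp"], dtype=float)
    bmi_rep = np.asarray(rep["bmi"], dtype=float)
    for values, bounds, name in ((sbp_rep, SBP_CATEGORY_BOUNDS, "sbp"),
                                 (bmi_rep, BMI_CATEGORY_BOUNDS, "bmi")):
        for v, (lo, hi) in zip(values, bounds):
            if not (lo <= v <= hi):
                raise ValidationError(
                    f"representative {name} value {v} outside category "
                    f"bounds [{lo}, {hi}]")

    heights = np.empty((2, _N_AGE))
    for s, sex in enumerate(SEXES):
        h = np.asarray(profile_config["heights"][sex], dtype=float)
        if ((h <= 1.2) | (h >= 2.2)).any():
            raise ValidationError(f"heights for {sex} outside (1.2, 2.2) m")
        heights[s] = h
    return RiskFactorMarginals(probs=probs, sbp_representative=sbp_rep,
                               bmi_representative=bmi_rep, heights=heights)


# ---------------------------------------------------------------------------
# consumption


@dataclass(frozen=True)
class ConsumptionProfile:
    """Mean daily 12-oz servings per sex x age group."""

    estimate_label: str
    servings: np.ndarray  # (2, 6)

    def for_stratum(self, sex: str, age_group: str) -> float:
        return float(self.servings[SEXES.index(sex), AGE_GROUPS.index(age_group)])


def generate_consumption_profiles(
    anchor_servings_women_35_44: float,
    age_sex_scaling: Mapping[str, object],
    seed: int | None = None,
    estimate_label: str = "custom",
) -> ConsumptionProfile:
    """Scale the women-35-44 anchor across sex/age strata.

    Servings for each stratum are ``anchor x scaling[sex][age]`` with the
    women 35-44 scaling fixed at 1.  Consumption for the 75+ groups is set
    equal to the 65-74 value of the same sex.
    """
    anchor = float(anchor_servings_women_35_44)
    if anchor < 0:
        raise ValidationError("anchor servings must be nonnegative")
    servings = np.empty((2, _N_AGE))
    for s, sex in enumerate(SEXES):
        scale = np.asarray(age_sex_scaling[sex], dtype=float)
        if scale.shape != (_N_AGE,):
            raise ConfigurationError(
                f"scaling for '{sex}' must cover all age groups")
        if (scale < 0).any():
            raise ValidationError(f"negative scaling factor for '{sex}'")
        servings[s] = anchor * scale
    # 75-84 and 85-94 mirror the 65-74 stratum
    servings[:, 4:] = servings[:, 3:4]
    return ConsumptionProfile(estimate_label=estimate_label, servings=servings)


def derive_high_estimate_anchor(
    total_soda_ml: float,
    regular_fraction: float,
    sales_ratio: float,
    population_ratio: float,
) -> float:
    """Sales-scaled daily servings for women 35-44.

    Starting from total (regular + diet) daily soda volume, keep the
    regular-soda fraction of sales, scale by the ratio of recent to survey-
    year sales, correct for population growth, and convert ml to 12-oz
    servings.
    """
    if total_soda_ml <= 0:
        raise ValidationError("total_soda_ml must be positive")
    if not (0 < regular_fraction <= 1):
        raise ValidationError("regular_fraction must be in (0, 1]")
    if sales_ratio <= 0:
        raise ValidationError("sales_ratio must be positive")
    if population_ratio <= 0:
        raise ValidationError("population_ratio must be positive")
    return (total_soda_ml * regular_fraction * sales_ratio
            / population_ratio / SERVING_ML)


# ---------------------------------------------------------------------------
# risk-function coefficients


@dataclass(frozen=True)
class RiskFunctionCoefficients:
    """Logistic coefficients (log-odds scale) with 95% CIs per outcome.

    ``values[outcome][term]`` is a float, or a length-3 array for the
    categorical terms (reference category first, coefficient 0).
    ``ci[outcome][term]`` holds matching (lo, hi) pairs.
    """

    values: dict[str, dict[str, object]]
    ci: dict[str, dict[str, object]]

    def get(self, outcome: str, term: str):
        try:
            return self.values[outcome][term]
        except KeyError as exc:
            raise ConfigurationError(
                f"coefficient set missing {outcome}/{term}") from exc

    def iter_parameters(self) -> Iterator[tuple[str, float, float, float]]:
        """Yield (path, mean, ci_lo, ci_hi) for every non-degenerate entry.

        Paths look like ``coef.incident_chd.intercept`` or
        ``coef.incident_chd.ldl.1``.  Reference-category zeros (degenerate
        CIs) are skipped: they are structural, not uncertain.
        """
        for outcome in ALL_OUTCOMES:
            terms = NO_CVD_TERMS if outcome in NO_CVD_OUTCOMES else POST_CVD_TERMS
            for term in terms:
                value = self.values[outcome][term]
                bounds = self.ci[outcome][term]
                if term in CATEGORICAL_TERMS:
                    for k, (v, (lo, hi)) in enumerate(zip(value, bounds)):
                        if lo != hi:
                            yield (f"coef.{outcome}.{term}.{k}", float(v),
                                   float(lo), float(hi))
                else:
                    lo, hi = bounds
                    if lo != hi:
                        yield (f"coef.{outcome}.{term}", float(value),
                               float(lo), float(hi))

    def with_updates(self, updates: Mapping[str, float]) -> "RiskFunctionCoefficients":
        """Return a copy with ``coef.*`` path entries replaced."""
        values = {o: dict(t) for o, t in self.values.items()}
        for o in values:
            for term in CATEGORICAL_TERMS:
                if term in values[o]:
                    values[o][term] = np.array(values[o][term], dtype=float)
        for path, new in updates.items():
            if not path.startswith("coef."):
                continue
            parts = path.split(".")
            _, outcome, term = parts[:3]
            if term in CATEGORICAL_TERMS:
                values[outcome][term][int(parts[3])] = new
            else:
                values[outcome][term] = float(new)
        return RiskFunctionCoefficients(values=values, ci=self.ci)


def generate_risk_function_coefficients(
    coef_config: Mapping, seed: int | None = None
) -> RiskFunctionCoefficients:
    """Materialize coefficient arrays from the ``coefficients`` config."""
    values: dict[str, dict[str, object]] = {}
    ci: dict[str, dict[str, object]] = {}
    for outcome in ALL_OUTCOMES:
        if outcome not in coef_config:
            raise ConfigurationError(f"coefficients missing outcome '{outcome}'")
        terms = NO_CVD_TERMS if outcome in NO_CVD_OUTCOMES else POST_CVD_TERMS
        values[outcome] = {}
        ci[outcome] = {}
        for term in terms:
            entry = coef_config[outcome].get(term)
            if entry is None:
                raise ConfigurationError(
                    f"coefficients.{outcome} missing term '{term}'")
            if term in CATEGORICAL_TERMS:
                values[outcome][term] = np.array(
                    [e["value"] for e in entry], dtype=float)
                ci[outcome][term] = [tuple(e["ci"]) for e in entry]
            else:
                values[outcome][term] = float(entry["value"])
                ci[outcome][term] = tuple(entry["ci"])
            # CIs must bracket their point estimates
            pairs = (ci[outcome][term] if term in CATEGORICAL_TERMS
                     else [ci[outcome][term]])
            vals = (values[outcome][term] if term in CATEGORICAL_TERMS
                    else [values[outcome][term]])
            for v, (lo, hi) in zip(np.atleast_1d(vals), pairs):
                if not (lo <= v <= hi):
                    raise ValidationError(
                        f"CI for {outcome}.{term} does not contain its value")
    return RiskFunctionCoefficients(values=values, ci=ci)


# ---------------------------------------------------------------------------
# bundle


@dataclass(frozen=True)
class ModelInputs:
    """Everything a simulation run consumes, generated from one config."""

    demography: DemographyTable
    marginals: RiskFactorMarginals
    consumption: dict[str, ConsumptionProfile]
    coefficients: RiskFunctionCoefficients
    prior_chd_prevalence: np.ndarray    # (2, 6)
    prior_stroke_prevalence: np.ndarray  # (2, 6)
    start_year: int
    horizon_years: int


def generate_inputs(cfg: Mapping, seed: int | None = None) -> ModelInputs:
    """Generate the full input bundle from a validated config mapping."""
    demo_cfg = cfg["demography"]
    demography = generate_demography(
        demo_cfg["base_counts"], demo_cfg["entrants"],
        int(demo_cfg["horizon_years"]), seed=seed,
        start_year=int(demo_cfg["start_year"]))
    marginals = generate_risk_factor_marginals(cfg["risk_factors"], seed=seed)
    consumption = {}
    for label in ("low", "high"):
        prof = cfg["consumption"][label]
        consumption[label] = generate_consumption_profiles(
            prof["anchor_servings"], prof["scaling"], seed=seed,
            estimate_label=label)
    if not np.all(consumption["high"].servings >= consumption["low"].servings):
        raise ValidationError(
            "high consumption estimate below low estimate in some stratum")
    coefficients = generate_risk_function_coefficients(cfg["coefficients"],
                                                       seed=seed)
    prev_chd = np.array([demo_cfg["prior_chd_prevalence"][s] for s in SEXES],
                        dtype=float)
    prev_stroke = np.array(
        [demo_cfg["prior_stroke_prevalence"][s] for s in SEXES], dtype=float)
    return ModelInputs(
        demography=demography, marginals=marginals, consumption=consumption,
        coefficients=coefficients, prior_chd_prevalence=prev_chd,
        prior_stroke_prevalence=prev_stroke,
        start_year=int(demo_cfg["start_year"]),
        horizon_years=int(demo_cfg["horizon_years"]))


# ---------------------------------------------------------------------------
# CSV serialization


def write_inputs_csv(inputs: ModelInputs, outdir: str | Path) -> dict[str, Path]:
    """Write one UTF-8 CSV per input table; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["demography"] = outdir / "demography.csv"
    inputs.demography.frame.to_csv(paths["demography"], index=False)

    rows = []
    for factor, cats in RISK_FACTORS.items():
        for s, sex in enumerate(SEXES):
            for a, group in enumerate(AGE_GROUPS):
                for k, cat in enumerate(cats):
                    rows.append({
                        "factor": factor, "sex": sex, "age_group": group,
                        "category": cat,
                        "probability": inputs.marginals.probs[factor][s, a, k],
                    })
    paths["marginals"] = outdir / "marginals.csv"
    pd.DataFrame(rows).to_csv(paths["marginals"], index=False)

    rows = []
    for label, profile in inputs.consumption.items():
        for s, sex in enumerate(SEXES):
            for a, group in enumerate(AGE_GROUPS):
                rows.append({
                    "estimate": label, "sex": sex, "age_group": group,
                    "servings_per_day": profile.servings[s, a],
                })
    paths["consumption"] = outdir / "consumption.csv"
    pd.DataFrame(rows).to_csv(paths["consumption"], index=False)

    rows = []
    for path, mean, lo, hi in inputs.coefficients.iter_parameters():
        rows.append({"parameter": path, "value": mean,
                     "ci_low": lo, "ci_high": hi})
    paths["coefficients"] = outdir / "coefficients.csv"
    pd.DataFrame(rows).to_csv(paths["coefficients"], index=False)
    return paths
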