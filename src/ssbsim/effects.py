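"""SSB-reduction effect pathways: servings -> SBP, BMI and diabetes risk.

A fractional reduction in daily SSB (sugar-sweetened soda) servings acts
through two pathways, both applied once in the first simulated year and
then held constant:

* a direct pathway — each 12-oz serving/day removed lowers SBP by a
  per-sex amount (0.78 mmHg men, 0.61 mmHg women) and divides the
  incident-diabetes relative risk of 1.19 per serving out of the hazard;
* a BMI-mediated pathway — uncompensated calories (150 kcal/serving, less
  the caloric-compensation fraction) accumulate for one year into a weight
  change at 3,500 kcal per pound, converted to kg/m^2 with per-stratum mean
  heights; each BMI unit moves SBP (1.43/1.24 mmHg by sex) and scales
  diabetes incidence by an age-dependent RR anchored at 1.17 for 55-64.

Direct and BMI-mediated diabetes effects compose multiplicatively on the
RR scale; the combined multiplier is applied to the annual incidence via
hazard scaling (h' = m*h), preserving RR semantics at small probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .constants import (
    AGE_GROUPS,
    BMI_CATEGORY_BOUNDS,
    BMI_PHYSIOLOGIC,
    SBP_CATEGORY_BOUNDS,
    SBP_PHYSIOLOGIC,
    SERVING_ML,
    SEXES,
)
from .errors import ValidationError
from .model_core import ModelState
from .synthetic_inputs import ConsumptionProfile, RiskFactorMarginals

logger = logging.getLogger(__name__)

_N_AGE = len(AGE_GROUPS)


@dataclass(frozen=True)
class EffectParameters:
    """Effect sizes (with 95% CIs) and caloric constants.

    ``sbp_direct`` and ``sbp_per_bmi`` map sex -> mmHg per serving/day and
    per kg/m^2.  ``rr_bmi_diabetes_anchor`` is the RR per BMI unit at the
    anchor age group, declining with age on the log scale at
    ``rr_bmi_log_slope_per_decade``.
    """

    sbp_direct: dict[str, float]
    rr_diabetes_per_serving: float
    sbp_per_bmi: dict[str, float]
    rr_bmi_diabetes_anchor: float
    rr_bmi_anchor_age_group: str = "55-64"
    rr_bmi_log_slope_per_decade: float = -0.04
    kcal_per_serving: float = 150.0
    kcal_per_pound: float = 3500.0
    pound_kg: float = 0.45359237
    serving_ml: float = SERVING_ML
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.rr_diabetes_per_serving <= 0 or self.rr_bmi_diabetes_anchor <= 0:
            raise ValidationError("relative risks must be positive")
        for const in (self.kcal_per_serving, self.kcal_per_pound, self.pound_kg):
            if const <= 0:
                raise ValidationError("caloric constants must be positive")
        for name, (lo, hi) in self.ci.items():
            mean = self._lookup(name)
            if not (lo <= mean <= hi):
                raise ValidationError(
                    f"CI for effect '{name}' does not contain its mean")

    def _lookup(self, name: str) -> float:
        mapping = {
            "effect.sbp_direct.men": self.sbp_direct["men"],
            "effect.sbp_direct.women": self.sbp_direct["women"],
            "effect.rr_diabetes_per_serving": self.rr_diabetes_per_serving,
            "effect.sbp_per_bmi.men": self.sbp_per_bmi["men"],
            "effect.sbp_per_bmi.women": self.sbp_per_bmi["women"],
            "effect.rr_bmi_diabetes_anchor": self.rr_bmi_diabetes_anchor,
        }
        return mapping[name]

    @classmethod
    def from_config(cls, effects_cfg: Mapping) -> "EffectParameters":
        rr_bmi = effects_cfg["rr_diabetes_per_bmi_unit"]
        ci = {
            "effect.sbp_direct.men": tuple(effects_cfg["sbp_direct"]["men"]["ci"]),
            "effect.sbp_direct.women": tuple(effects_cfg["sbp_direct"]["women"]["ci"]),
            "effect.rr_diabetes_per_serving": tuple(
                effects_cfg["rr_diabetes_per_serving"]["ci"]),
            "effect.sbp_per_bmi.men": tuple(
                effects_cfg["sbp_per_bmi_unit"]["men"]["ci"]),
            "effect.sbp_per_bmi.women": tuple(
                effects_cfg["sbp_per_bmi_unit"]["women"]["ci"]),
            "effect.rr_bmi_diabetes_anchor": tuple(rr_bmi["ci"]),
        }
        return cls(
            sbp_direct={s: effects_cfg["sbp_direct"][s]["mean"] for s in SEXES},
            rr_diabetes_per_serving=effects_cfg["rr_diabetes_per_serving"]["mean"],
            sbp_per_bmi={s: effects_cfg["sbp_per_bmi_unit"][s]["mean"]
                         for s in SEXES},
            rr_bmi_diabetes_anchor=rr_bmi["mean"],
            rr_bmi_anchor_age_group=rr_bmi.get("anchor_age_group", "55-64"),
            rr_bmi_log_slope_per_decade=rr_bmi.get("log_slope_per_decade", -0.04),
            kcal_per_serving=effects_cfg["kcal_per_serving"],
            kcal_per_pound=effects_cfg["kcal_per_pound"],
            pound_kg=effects_cfg["pound_kg"],
            ci=ci,
        )

    def rr_bmi_by_age(self) -> np.ndarray:
        """RR of diabetes per +1 BMI unit for each age decade, shape (6,)."""
        anchor_index = AGE_GROUPS.index(self.rr_bmi_anchor_age_group)
        offsets = np.arange(_N_AGE) - anchor_index
        return np.exp(np.log(self.rr_bmi_diabetes_anchor)
                      + self.rr_bmi_log_slope_per_decade * offsets)

    def iter_parameters(self):
        """Yield (path, mean, lo, hi) for the Monte Carlo varied effects."""
        for name, bounds in self.ci.items():
            yield (name, self._lookup(name), bounds[0], bounds[1])

    def with_updates(self, updates: Mapping[str, float]) -> "EffectParameters":
        """Return a copy with ``effect.*`` path entries replaced."""
        sbp_direct = dict(self.sbp_direct)
        sbp_per_bmi = dict(self.sbp_per_bmi)
        rr_serving = self.rr_diabetes_per_serving
        rr_bmi = self.rr_bmi_diabetes_anchor
        for path, value in updates.items():
            if path == "effect.sbp_direct.men":
                sbp_direct["men"] = value
            elif path == "effect.sbp_direct.women":
                sbp_direct["women"] = value
            elif path == "effect.sbp_per_bmi.men":
                sbp_per_bmi["men"] = value
            elif path == "effect.sbp_per_bmi.women":
                sbp_per_bmi["women"] = value
            elif path == "effect.rr_diabetes_per_serving":
                rr_serving = value
            elif path == "effect.rr_bmi_diabetes_anchor":
                rr_bmi = value
        return replace(self, sbp_direct=sbp_direct, sbp_per_bmi=sbp_per_bmi,
                       rr_diabetes_per_serving=rr_serving,
                       rr_bmi_diabetes_anchor=rr_bmi, ci={})


@dataclass(frozen=True)
class InterventionShift:
    """Per sex x age risk-factor shifts implied by a consumption change."""

    delta_servings: np.ndarray        # (2, 6), <= 0 for a reduction
    delta_bmi: np.ndarray             # (2, 6) kg/m^2
    delta_sbp: np.ndarray             # (2, 6) mmHg, total of both pathways
    diabetes_multiplier: np.ndarray   # (2, 6), 1 = no change

    @classmethod
    def identity(cls) -> "InterventionShift":
        zero = np.zeros((2, _N_AGE))
        return cls(delta_servings=zero.copy(), delta_bmi=zero.copy(),
                   delta_sbp=zero.copy(),
                   diabetes_multiplier=np.ones((2, _N_AGE)))


# ---------------------------------------------------------------------------
# pathway operations


def reduction_to_delta_servings(
    profile: ConsumptionProfile, reduction_fraction: float
) -> np.ndarray:
    """Change in daily servings per stratum: -fraction x baseline."""
    if not (0 <= reduction_fraction <= 1):
        raise ValidationError("reduction fraction must be in [0, 1]")
    return -reduction_fraction * profile.servings


def tax_to_reduction(
    tax_fraction: float,
    elasticity: float | None = None,
    mode: str = "one_to_one",
) -> float:
    """Consumption reduction implied by an ad-valorem tax.

    ``one_to_one`` passes the tax through directly (soda demand elasticity
    in Argentina is close to -1, so a 10% tax maps to a 10% reduction);
    ``elastic`` returns min(1, |elasticity| x tax).
    """
    if tax_fraction < 0:
        raise ValidationError("tax fraction must be nonnegative")
    if mode == "one_to_one":
        return min(1.0, tax_fraction)
    if mode == "elastic":
        if elasticity is None:
            raise ValidationError("elastic mode requires an elasticity")
        if elasticity >= 0:
            raise ValidationError("demand elasticity must be negative")
        return min(1.0, abs(elasticity) * tax_fraction)
    raise ValidationError(f"unknown tax mode '{mode}'")


def delta_servings_to_delta_bmi(
    delta_servings, compensation_fraction: float, height_m,
    params: EffectParameters,
):
    """BMI change from one year of uncompensated caloric imbalance.

    daily kcal = delta_servings x kcal_per_serving x (1 - compensation);
    weight (kg) = daily kcal x 365 / kcal_per_pound x pound_kg;
    delta BMI = weight / height^2.  Scalar or array inputs broadcast.
    """
    if not (0 <= compensation_fraction <= 1):
        raise ValidationError("compensation fraction must be in [0, 1]")
    height = np.asarray(height_m, dtype=float)
    if (height <= 0).any():
        raise ValidationError("height must be positive")
    daily_kcal = (np.asarray(delta_servings, dtype=float)
                  * params.kcal_per_serving * (1.0 - compensation_fraction))
    weight_kg = daily_kcal * 365.0 / params.kcal_per_pound * params.pound_kg
    out = weight_kg / height ** 2
    return float(out) if np.isscalar(delta_servings) and height.ndim == 0 else out


def compose_sbp_shift(
    delta_servings, delta_bmi, sex: str, params: EffectParameters
):
    """Total SBP change: direct per-serving plus BMI-mediated, additive."""
    if sex not in SEXES:
        raise ValidationError(f"unknown sex '{sex}'")
    return (params.sbp_direct[sex] * np.asarray(delta_servings, dtype=float)
            + params.sbp_per_bmi[sex] * np.asarray(delta_bmi, dtype=float))


def compose_diabetes_multiplier(
    delta_servings, delta_bmi, age_group: str, params: EffectParameters
):
    """Combined diabetes-incidence multiplier on the RR scale.

    multiplier = RR_serving^delta_servings x RR_bmi(age)^delta_bmi; both
    exponents are negative for a reduction, so the multiplier is <= 1.
    """
    if age_group not in AGE_GROUPS:
        raise ValidationError(f"unknown age group '{age_group}'")
    rr_bmi = params.rr_bmi_by_age()[AGE_GROUPS.index(age_group)]
    return (params.rr_diabetes_per_serving ** np.asarray(delta_servings, float)
            * rr_bmi ** np.asarray(delta_bmi, float))


def build_intervention_shift(
    profile: ConsumptionProfile,
    reduction_fraction: float,
    compensation_fraction: float,
    marginals: RiskFactorMarginals,
    params: EffectParameters,
) -> InterventionShift:
    """Assemble the full per-stratum shift for a scenario."""
    delta_serv = reduction_to_delta_servings(profile, reduction_fraction)
    delta_bmi = delta_servings_to_delta_bmi(
        delta_serv, compensation_fraction, marginals.heights, params)
    delta_sbp = np.empty((2, _N_AGE))
    multiplier = np.empty((2, _N_AGE))
    rr_bmi = params.rr_bmi_by_age()
    for s, sex in enumerate(SEXES):
        delta_sbp[s] = compose_sbp_shift(delta_serv[s], delta_bmi[s], sex, params)
        multiplier[s] = (params.rr_diabetes_per_serving ** delta_serv[s]
                         * rr_bmi ** delta_bmi[s])
    return InterventionShift(delta_servings=delta_serv, delta_bmi=delta_bmi,
                             delta_sbp=delta_sbp,
                             diabetes_multiplier=multiplier)


def apply_shift_to_population(
    state: ModelState, shift: InterventionShift
) -> ModelState:
    """Move each stratum's continuous SBP/BMI values and attach the
    diabetes multiplier; person counts are untouched.

    Shifted values escaping physiologic bounds are clamped (and logged).
    """
    new = state.copy()
    new.sbp_values = new.sbp_values + shift.delta_sbp[:, :, None]
    new.bmi_values = new.bmi_values + shift.delta_bmi[:, :, None]
    clamped = 0
    for values, bounds in ((new.sbp_values, SBP_PHYSIOLOGIC),
                           (new.bmi_values, BMI_PHYSIOLOGIC)):
        below = values < bounds[0]
        above = values > bounds[1]
        clamped += int(below.sum() + above.sum())
        np.clip(values, bounds[0], bounds[1], out=values)
    if clamped:
        logger.warning("clamped %d shifted continuous values to physiologic "
                       "bounds", clamped)
    new.diabetes_hazard_multiplier = (
        state.diabetes_hazard_multiplier * shift.diabetes_multiplier)
    return new


def category_labels(state: ModelState) -> dict[str, np.ndarray]:
    """Display category labels recomputed from (shifted) continuous values.

    Returns ``{"sbp": (2, 6, 3) str array, "bmi": ...}``: the label each
    original category's representative value now falls in.
    """
    def classify(values, bounds, labels):
        out = np.empty(values.shape, dtype=object)
        for k, (lo, hi) in enumerate(bounds):
            mask = (values >= lo) & (values < hi) if k < len(bounds) - 1 \
                else (values >= lo)
            out[mask] = labels[k]
        out[values < bounds[0][0]] = labels[0]
        return out

    from .constants import BMI_CATEGORIES, SBP_CATEGORIES
    return {
        "sbp": classify(state.sbp_values, SBP_CATEGORY_BOUNDS, SBP_CATEGORIES),
        "bmi": classify(state.bmi_values, BMI_CATEGORY_BOUNDS, BMI_CATEGORIES),
    }
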