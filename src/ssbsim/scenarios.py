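"""Scenario definitions, execution, and prevented-case comparison.

The canonical grid crosses consumption-reduction fractions {10%, 20%} (plus
an extreme 40%), caloric-compensation fractions {0%, 39%, 100%}, and the
"low"/"high" baseline consumption estimates, each run against the shared
base case of no change in consumption over 2015-2024.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .constants import (
    AGE_GROUPS,
    DEFAULT_HORIZON_YEARS,
    DEFAULT_START_YEAR,
    SEXES,
    TABLE_OUTCOMES,
)
from .effects import (
    EffectParameters,
    apply_shift_to_population,
    build_intervention_shift,
)
from .errors import ConfigurationError, ValidationError
from .model_core import OutcomeLedger, build_initial_state, run_horizon
from .synthetic_inputs import ModelInputs


@dataclass(frozen=True)
class Scenario:
    """One intervention scenario (immutable)."""

    reduction_fraction: float
    compensation_fraction: float
    consumption_estimate: str
    label: str
    start_year: int = DEFAULT_START_YEAR
    horizon_years: int = DEFAULT_HORIZON_YEARS

    def __post_init__(self):
        if not (0 <= self.reduction_fraction <= 1):
            raise ValidationError("reduction fraction must be in [0, 1]")
        if not (0 <= self.compensation_fraction <= 1):
            raise ValidationError("compensation fraction must be in [0, 1]")
        if self.consumption_estimate not in ("low", "high"):
            raise ValidationError("consumption estimate must be low or high")
        if self.horizon_years < 1:
            raise ValidationError("horizon must be >= 1 year")

    @property
    def is_base_case(self) -> bool:
        return self.reduction_fraction == 0


def base_scenario(consumption_estimate: str = "low") -> Scenario:
    return Scenario(0.0, 0.0, consumption_estimate,
                    label=f"base_{consumption_estimate}")


def default_grid(include_extreme: bool = False) -> list[Scenario]:
    """The 12-scenario grid; optionally adds the 40% x 39% extreme runs."""
    scenarios = []
    reductions = [0.10, 0.20]
    for reduction in reductions:
        for compensation in (0.0, 0.39, 1.0):
            for estimate in ("low", "high"):
                scenarios.append(Scenario(
                    reduction, compensation, estimate,
                    label=(f"r{int(round(reduction * 100))}"
                           f"_c{int(round(compensation * 100))}_{estimate}")))
    if include_extreme:
        for estimate in ("low", "high"):
            scenarios.append(Scenario(0.40, 0.39, estimate,
                                      label=f"r40_c39_{estimate}"))
    return scenarios


def run_scenario(
    scenario: Scenario,
    inputs: ModelInputs,
    effect_params: EffectParameters,
) -> OutcomeLedger:
    """Run one scenario (or the base case when reduction is 0).

    Base and intervention runs share identical demography, marginals and
    coefficients; only the one-time intervention shift differs.
    """
    if scenario.consumption_estimate not in inputs.consumption:
        raise ConfigurationError(
            f"inputs lack consumption estimate "
            f"'{scenario.consumption_estimate}'")
    state = build_initial_state(inputs)
    if not scenario.is_base_case:
        shift = build_intervention_shift(
            inputs.consumption[scenario.consumption_estimate],
            scenario.reduction_fraction, scenario.compensation_fraction,
            inputs.marginals, effect_params)
        state = apply_shift_to_population(state, shift)
    return run_horizon(state, inputs.coefficients, inputs.demography,
                       marginals=inputs.marginals,
                       horizon_years=scenario.horizon_years,
                       start_year=scenario.start_year)


@dataclass(frozen=True)
class ComparisonResult:
    """Prevented cases of a scenario against its base case.

    ``outcomes[outcome]`` holds base, scenario, prevented (= base -
    scenario) and percent_change (= 100 x prevented / base) totals;
    ``prevented_by_stratum``/``percent_by_stratum`` give the same per
    (sex, age) as (2, 6) arrays.
    """

    scenario_label: str
    outcomes: dict[str, dict[str, float]]
    prevented_by_stratum: dict[str, np.ndarray]
    percent_by_stratum: dict[str, np.ndarray]
    base_totals: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for outcome, vals in self.outcomes.items():
            rows.append({"scenario": self.scenario_label, "outcome": outcome,
                         **vals})
        return pd.DataFrame(rows)


def compare(base: OutcomeLedger, scenario: OutcomeLedger,
            scenario_label: str = "scenario") -> ComparisonResult:
    """Exact prevented-case accounting; rounding lives in reporting."""
    if base.start_year != scenario.start_year:
        raise ValidationError("ledgers cover different horizons")
    for outcome in TABLE_OUTCOMES:
        if base.annual[outcome].shape != scenario.annual[outcome].shape:
            raise ValidationError("ledger stratification mismatch")
    outcomes = {}
    prevented_strat = {}
    percent_strat = {}
    for outcome in TABLE_OUTCOMES:
        b = base.cumulative(outcome)
        s = scenario.cumulative(outcome)
        prevented = b - s
        outcomes[outcome] = {
            "base": b, "scenario": s, "prevented": prevented,
            "percent_change": 100.0 * prevented / b if b > 0 else float("nan"),
        }
        b_strat = base.cumulative(outcome, by_stratum=True)
        s_strat = scenario.cumulative(outcome, by_stratum=True)
        prevented_strat[outcome] = b_strat - s_strat
        with np.errstate(invalid="ignore", divide="ignore"):
            percent_strat[outcome] = np.where(
                b_strat > 0, 100.0 * (b_strat - s_strat)
                / np.where(b_strat > 0, b_strat, 1.0), np.nan)
    return ComparisonResult(
        scenario_label=scenario_label, outcomes=outcomes,
        prevented_by_stratum=prevented_strat,
        percent_by_stratum=percent_strat,
        base_totals={o: outcomes[o]["base"] for o in TABLE_OUTCOMES})


def run_grid(
    scenarios: Iterable[Scenario],
    inputs: ModelInputs,
    effect_params: EffectParameters,
) -> dict[str, ComparisonResult]:
    """Run a list of scenarios against cached base cases.

    One base-case ledger is computed per consumption-estimate label and
    reused bit-identically for every scenario sharing that estimate.
    Results preserve scenario order; duplicate labels are an error.
    """
    scenarios = list(scenarios)
    if not scenarios:
        raise ValidationError("scenario list is empty")
    labels = [s.label for s in scenarios]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate scenario labels")
    base_cache: dict[str, OutcomeLedger] = {}
    results: dict[str, ComparisonResult] = {}
    for scenario in scenarios:
        estimate = scenario.consumption_estimate
        if estimate not in base_cache:
            base_cache[estimate] = run_scenario(
                base_scenario(estimate), inputs, effect_params)
        if scenario.is_base_case:
            ledger = base_cache[estimate]
        else:
            ledger = run_scenario(scenario, inputs, effect_params)
        results[scenario.label] = compare(base_cache[estimate], ledger,
                                          scenario_label=scenario.label)
    return results


def grid_frame(results: Mapping[str, ComparisonResult]) -> pd.DataFrame:
    """All comparisons as one tidy frame."""
    return pd.concat([r.to_frame() for r in results.values()],
                     ignore_index=True)
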