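"""Monte Carlo probabilistic sensitivity analysis with 95% UIs.

Every varied parameter (the SSB effect sizes and the risk-function
coefficients) carries a mean and a 95% CI.  Each iteration draws a standard
normal deviate per parameter and scales it to the CI: additive parameters
as ``mean + z (hi - lo) / (2 x 1.96)``, relative risks (and additive
parameters with clearly asymmetric, positive CIs) on the log scale with a
log-CI-derived SE.  Within an iteration the same draw drives the base-case
and every intervention run (paired design), so parameter uncertainty that
moves both runs together cancels out of the prevented-case difference.
95% uncertainty intervals are the empirical 2.5th/97.5th percentiles of
prevented cases across iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .constants import TABLE_OUTCOMES
from .effects import EffectParameters
from .errors import ValidationError
from .model_core import OutcomeLedger
from .scenarios import Scenario, base_scenario, compare, run_scenario
from .synthetic_inputs import ModelInputs

logger = logging.getLogger(__name__)

Z_95 = float(norm.ppf(0.975))  # 1.959964...

#: fraction of the CI width by which the half-widths may differ before a
#: positive additive parameter is treated as log-symmetric
_ASYMMETRY_TOLERANCE = 0.05


@dataclass(frozen=True)
class ParamSpec:
    """One varied parameter: mean, 95% CI and sampling scale."""

    name: str
    mean: float
    ci_low: float
    ci_high: float
    scale: str = "auto"  # "normal", "log" or "auto"

    def __post_init__(self):
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValidationError(
                f"CI ({self.ci_low}, {self.ci_high}) does not contain mean "
                f"{self.mean} for '{self.name}'")
        if self.scale not in ("normal", "log", "auto"):
            raise ValidationError(f"unknown scale '{self.scale}'")

    def resolved_scale(self, strict_normal: bool = False) -> str:
        if strict_normal:
            return "normal"
        if self.scale != "auto":
            return self.scale
        width = self.ci_high - self.ci_low
        if width == 0:
            return "normal"
        asymmetry = abs((self.ci_high - self.mean) - (self.mean - self.ci_low))
        if asymmetry / width > _ASYMMETRY_TOLERANCE and self.ci_low > 0:
            return "log"
        return "normal"

    def sd(self, strict_normal: bool = False) -> float:
        """CI-implied standard deviation on the sampling scale."""
        if self.resolved_scale(strict_normal) == "log":
            return (np.log(self.ci_high) - np.log(self.ci_low)) / (2 * Z_95)
        return (self.ci_high - self.ci_low) / (2 * Z_95)

    def value_for(self, z: float, strict_normal: bool = False) -> float:
        if self.resolved_scale(strict_normal) == "log":
            return float(np.exp(np.log(self.mean) + z * self.sd(strict_normal)))
        return float(self.mean + z * self.sd(strict_normal))


@dataclass(frozen=True)
class ParameterDraw:
    """Sampled values for every varied parameter in one iteration."""

    iteration: int
    values: dict[str, float]


def default_param_specs(
    inputs: ModelInputs, effect_params: EffectParameters
) -> list[ParamSpec]:
    """Specs for all default varied parameters, in deterministic order.

    Relative risks are always log-sampled; additive effect sizes are
    normal unless their CI is clearly asymmetric and positive (then log).
    """
    specs: list[ParamSpec] = []
    for name, mean, lo, hi in effect_params.iter_parameters():
        scale = "log" if name.startswith("effect.rr") else "auto"
        specs.append(ParamSpec(name, mean, lo, hi, scale=scale))
    for name, mean, lo, hi in inputs.coefficients.iter_parameters():
        specs.append(ParamSpec(name, mean, lo, hi, scale="normal"))
    return specs


def draw_parameters(
    param_specs: Sequence[ParamSpec],
    n_iterations: int,
    seed: int,
    strict_normal: bool = False,
) -> list[ParameterDraw]:
    """Deterministic scaled-normal draws for every parameter."""
    if n_iterations < 1:
        raise ValidationError("need at least one iteration")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_iterations, len(param_specs)))
    draws = []
    for i in range(n_iterations):
        values = {spec.name: spec.value_for(z[i, j], strict_normal)
                  for j, spec in enumerate(param_specs)}
        draws.append(ParameterDraw(iteration=i, values=values))
    return draws


def percentile_interval(values, level: float = 0.95) -> tuple[float, float]:
    """Empirical central interval with linear interpolation."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("need at least two values for an interval")
    if not (0 < level < 1):
        raise ValidationError("level must be in (0, 1)")
    alpha = 100 * (1 - level) / 2
    lo, hi = np.percentile(values, [alpha, 100 - alpha], method="linear")
    return float(lo), float(hi)


@dataclass(frozen=True)
class UncertaintyResult:
    """Point estimates, 95% UIs and retained iteration values.

    ``samples[label][outcome]`` is the vector of prevented cases across the
    successful iterations; ``point``/``ui`` index the same way.
    """

    scenario_labels: list[str]
    outcomes: tuple[str, ...]
    point: dict[str, dict[str, float]]
    ui: dict[str, dict[str, tuple[float, float]]]
    samples: dict[str, dict[str, np.ndarray]]
    n_iterations: int
    n_failed: int
    seed: int
    level: float = 0.95

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label in self.scenario_labels:
            for outcome in self.outcomes:
                lo, hi = self.ui[label][outcome]
                rows.append({
                    "scenario": label, "outcome": outcome,
                    "prevented": self.point[label][outcome],
                    "ui_low": lo, "ui_high": hi,
                })
        return pd.DataFrame(rows)

    def iteration_frame(self) -> pd.DataFrame:
        """Long-format iteration-level outcomes for external audit."""
        rows = []
        for label in self.scenario_labels:
            for outcome in self.outcomes:
                for i, v in enumerate(self.samples[label][outcome]):
                    rows.append({"iteration": i, "scenario": label,
                                 "outcome": outcome, "value": v})
        return pd.DataFrame(rows)


def _perturbed(inputs: ModelInputs, effect_params: EffectParameters,
               values: Mapping[str, float]
               ) -> tuple[ModelInputs, EffectParameters]:
    from dataclasses import replace
    coef = inputs.coefficients.with_updates(values)
    new_inputs = replace(inputs, coefficients=coef)
    return new_inputs, effect_params.with_updates(values)


def run_monte_carlo(
    scenarios: Iterable[Scenario],
    inputs: ModelInputs,
    effect_params: EffectParameters,
    n_iterations: int = 1000,
    seed: int = 0,
    param_specs: Sequence[ParamSpec] | None = None,
    strict_normal: bool = False,
) -> UncertaintyResult:
    """Paired Monte Carlo over the varied parameters.

    Per iteration one base case per consumption-estimate label is run with
    the iteration's coefficients and shared by every scenario with that
    label.  Iterations that fail are recorded and excluded; more than 1%
    failures aborts the analysis.
    """
    scenarios = list(scenarios)
    if not scenarios:
        raise ValidationError("scenario list is empty")
    if n_iterations < 2:
        raise ValidationError("need at least two iterations")
    if param_specs is None:
        param_specs = default_param_specs(inputs, effect_params)
    draws = draw_parameters(param_specs, n_iterations, seed, strict_normal)

    labels = [s.label for s in scenarios]
    collected: dict[str, dict[str, list[float]]] = {
        label: {o: [] for o in TABLE_OUTCOMES} for label in labels}
    n_failed = 0
    for draw in draws:
        try:
            it_inputs, it_effects = _perturbed(inputs, effect_params,
                                               draw.values)
            base_cache: dict[str, OutcomeLedger] = {}
            for scenario in scenarios:
                estimate = scenario.consumption_estimate
                if estimate not in base_cache:
                    base_cache[estimate] = run_scenario(
                        base_scenario(estimate), it_inputs, it_effects)
                ledger = run_scenario(scenario, it_inputs, it_effects)
                result = compare(base_cache[estimate], ledger, scenario.label)
                for outcome in TABLE_OUTCOMES:
                    collected[scenario.label][outcome].append(
                        result.outcomes[outcome]["prevented"])
        except Exception as exc:  # noqa: BLE001 - failures are data here
            n_failed += 1
            logger.warning("iteration %d failed and was excluded: %s",
                           draw.iteration, exc)
            if n_failed > 0.01 * n_iterations:
                raise RuntimeError(
                    f"{n_failed} of {n_iterations} Monte Carlo iterations "
                    "failed (>1%); aborting") from exc

    # point estimates at the parameter means
    point: dict[str, dict[str, float]] = {}
    base_cache = {}
    for scenario in scenarios:
        estimate = scenario.consumption_estimate
        if estimate not in base_cache:
            base_cache[estimate] = run_scenario(base_scenario(estimate),
                                                inputs, effect_params)
        ledger = run_scenario(scenario, inputs, effect_params)
        result = compare(base_cache[estimate], ledger, scenario.label)
        point[scenario.label] = {
            o: result.outcomes[o]["prevented"] for o in TABLE_OUTCOMES}

    samples = {label: {o: np.asarray(v) for o, v in per.items()}
               for label, per in collected.items()}
    ui = {label: {o: percentile_interval(samples[label][o])
                  for o in TABLE_OUTCOMES} for label in labels}
    return UncertaintyResult(
        scenario_labels=labels, outcomes=TABLE_OUTCOMES, point=point, ui=ui,
        samples=samples, n_iterations=n_iterations, n_failed=n_failed,
        seed=seed)
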