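"""Cell-based Markov engine for CVD/diabetes incidence and mortality.

The population lives in three pools:

* ``no_cvd`` — shape (2, 6, 3, 3, 3, 3, 2, 3): sex, age decade and the six
  risk-factor axes (SBP, LDL, HDL, smoking, diabetes, BMI);
* ``prior_chd`` and ``prior_stroke`` — shape (2, 6): survivors of a first
  CHD event or stroke, stratified by sex and age only.

Each annual cycle, CVD-free cells face competing annual probabilities of
incident CHD, incident stroke and non-CVD death; event survivors move to
the matching prior-CVD pool.  Among event-free survivors, non-diabetic
cells face incident diabetes, which flips the diabetes axis from the next
cycle onward.  Prior-CVD pools face recurrent-event rates and competing
CVD/non-CVD death rates.  After transitions, one tenth of every decade cell
is promoted to the next decade (uniform age mixing within decades), one
tenth of the 85-94 group exits at 95, and new 35-year-olds enter the
CVD-free pool with the 35-44 risk-factor distribution.

All accounting is deterministic expected-value (compartmental): counts are
nonnegative reals and every flow is linear in the cell counts, so on a toy
population the whole year-update is a fixed transition matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .constants import (
    AGE_GROUPS,
    AGE_MIDPOINTS,
    AGING_FRACTION,
    ALL_OUTCOMES,
    BMI_PHYSIOLOGIC,
    NO_CVD_OUTCOMES,
    POST_CVD_OUTCOMES,
    REPORTED_OUTCOMES,
    RISK_FACTORS,
    SBP_PHYSIOLOGIC,
    SEXES,
)
from .errors import ConfigurationError, ValidationError
from .synthetic_inputs import (
    DemographyTable,
    ModelInputs,
    RiskFactorMarginals,
    RiskFunctionCoefficients,
)

logger = logging.getLogger(__name__)

_N_AGE = len(AGE_GROUPS)
_CELL_SHAPE = (2, _N_AGE, 3, 3, 3, 3, 2, 3)


# ---------------------------------------------------------------------------
# state


@dataclass
class ModelState:
    """Population cell counts plus the continuous values attached to cells.

    ``sbp_values``/``bmi_values`` have shape (2, 6, 3): the representative
    continuous value of each SBP/BMI category per sex and age (an
    intervention shifts these).  ``diabetes_hazard_multiplier`` (2, 6)
    scales the incident-diabetes hazard of every cell in the stratum; 1 in
    the base case.
    """

    no_cvd: np.ndarray
    prior_chd: np.ndarray
    prior_stroke: np.ndarray
    sbp_values: np.ndarray
    bmi_values: np.ndarray
    diabetes_hazard_multiplier: np.ndarray = field(
        default_factory=lambda: np.ones((2, _N_AGE)))

    def copy(self) -> "ModelState":
        return ModelState(
            no_cvd=self.no_cvd.copy(), prior_chd=self.prior_chd.copy(),
            prior_stroke=self.prior_stroke.copy(),
            sbp_values=self.sbp_values.copy(),
            bmi_values=self.bmi_values.copy(),
            diabetes_hazard_multiplier=self.diabetes_hazard_multiplier.copy())

    def total_population(self) -> float:
        return float(self.no_cvd.sum() + self.prior_chd.sum()
                     + self.prior_stroke.sum())

    def population_by_stratum(self) -> np.ndarray:
        """Persons per (sex, age), all pools combined."""
        axes = tuple(range(2, self.no_cvd.ndim))
        return self.no_cvd.sum(axis=axes) + self.prior_chd + self.prior_stroke

    def validate(self) -> None:
        if self.no_cvd.shape != _CELL_SHAPE:
            raise ValidationError(f"no_cvd must have shape {_CELL_SHAPE}")
        for arr, name in ((self.no_cvd, "no_cvd"),
                          (self.prior_chd, "prior_chd"),
                          (self.prior_stroke, "prior_stroke")):
            if (arr < 0).any():
                raise ValidationError(f"negative count in {name}")


@dataclass(frozen=True)
class PopulationCell:
    """A single stratum, mainly for scalar risk evaluation and testing."""

    sex: str
    age_group: str
    cvd_state: str = "no_prior_cvd"  # or "prior_chd" / "prior_stroke"
    risk_profile: Mapping[str, str] | None = None
    sbp: float = 120.0
    bmi: float = 25.0
    count: float = 0.0

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex '{self.sex}'")
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(f"unknown age group '{self.age_group}'")
        if self.count < 0:
            raise ValidationError("cell count must be nonnegative")
        if not (SBP_PHYSIOLOGIC[0] <= self.sbp <= SBP_PHYSIOLOGIC[1]):
            raise ValidationError("SBP outside physiologic bounds")
        if not (BMI_PHYSIOLOGIC[0] <= self.bmi <= BMI_PHYSIOLOGIC[1]):
            raise ValidationError("BMI outside physiologic bounds")


def build_initial_state(inputs: ModelInputs) -> ModelState:
    """Split the base-year population into the three pools.

    Prior-CVD prevalences are removed from each sex/age stratum first; the
    CVD-free remainder is spread over the 486 risk-factor combinations by
    the product of the categorical marginals.
    """
    counts = inputs.demography.base_counts
    prev_chd = inputs.prior_chd_prevalence
    prev_stroke = inputs.prior_stroke_prevalence
    if ((prev_chd + prev_stroke) > 1).any():
        raise ValidationError("prior-CVD prevalences sum above 1")
    free = counts * (1 - prev_chd - prev_stroke)
    joint = inputs.marginals.joint_all()
    no_cvd = free[:, :, None, None, None, None, None, None] * joint
    sbp_values = np.broadcast_to(
        inputs.marginals.sbp_representative, (2, _N_AGE, 3)).copy()
    bmi_values = np.broadcast_to(
        inputs.marginals.bmi_representative, (2, _N_AGE, 3)).copy()
    return ModelState(
        no_cvd=no_cvd,
        prior_chd=counts * prev_chd,
        prior_stroke=counts * prev_stroke,
        sbp_values=sbp_values,
        bmi_values=bmi_values,
    )


# ---------------------------------------------------------------------------
# risk functions


def annual_risk(
    cell: PopulationCell,
    coefficients: RiskFunctionCoefficients,
    outcome: str,
) -> float:
    """Annual probability of ``outcome`` for one cell (logistic link).

    The linear predictor is centered at a reference of women, age 40,
    SBP 120 mmHg, BMI 25 kg/m^2, first category of each categorical factor
    and no diabetes, so an all-zero coefficient set gives probability 0.5
    and the intercept alone sets the reference probability.
    """
    if outcome not in ALL_OUTCOMES:
        raise ConfigurationError(f"unknown outcome '{outcome}'")
    s = SEXES.index(cell.sex)
    a = AGE_GROUPS.index(cell.age_group)
    lp = (coefficients.get(outcome, "intercept")
          + coefficients.get(outcome, "male") * (1.0 if s == 0 else 0.0)
          + coefficients.get(outcome, "age_per_year") * (AGE_MIDPOINTS[a] - 40.0))
    if outcome in NO_CVD_OUTCOMES:
        profile = dict(cell.risk_profile or {})
        lp += coefficients.get(outcome, "sbp_per_mmhg") * (cell.sbp - 120.0)
        lp += coefficients.get(outcome, "bmi_per_unit") * (cell.bmi - 25.0)
        for term in ("ldl", "hdl", "smoking"):
            cats = RISK_FACTORS[term]
            label = profile.get(term, cats[0])
            lp += coefficients.get(outcome, term)[cats.index(label)]
        diabetic = profile.get("diabetes", "no") == "yes"
        lp += coefficients.get(outcome, "diabetes") * (1.0 if diabetic else 0.0)
    return float(expit(lp))


def _no_cvd_probability_array(
    state: ModelState, coefficients: RiskFunctionCoefficients, outcome: str
) -> np.ndarray:
    """Vectorized annual probabilities over the full no-CVD cell array."""
    male = np.array([1.0, 0.0]).reshape(2, 1, 1, 1, 1, 1, 1, 1)
    age = (np.asarray(AGE_MIDPOINTS) - 40.0).reshape(1, _N_AGE, 1, 1, 1, 1, 1, 1)
    sbp = (state.sbp_values - 120.0).reshape(2, _N_AGE, 3, 1, 1, 1, 1, 1)
    bmi = (state.bmi_values - 25.0).reshape(2, _N_AGE, 1, 1, 1, 1, 1, 3)
    c = coefficients
    lp = (c.get(outcome, "intercept")
          + c.get(outcome, "male") * male
          + c.get(outcome, "age_per_year") * age
          + c.get(outcome, "sbp_per_mmhg") * sbp
          + c.get(outcome, "bmi_per_unit") * bmi
          + np.asarray(c.get(outcome, "ldl")).reshape(1, 1, 1, 3, 1, 1, 1, 1)
          + np.asarray(c.get(outcome, "hdl")).reshape(1, 1, 1, 1, 3, 1, 1, 1)
          + np.asarray(c.get(outcome, "smoking")).reshape(1, 1, 1, 1, 1, 3, 1, 1)
          + c.get(outcome, "diabetes")
          * np.array([0.0, 1.0]).reshape(1, 1, 1, 1, 1, 1, 2, 1))
    return expit(np.broadcast_to(lp, _CELL_SHAPE))


def _post_cvd_probability_array(
    coefficients: RiskFunctionCoefficients, outcome: str
) -> np.ndarray:
    """Annual probabilities for a prior-CVD pool, shape (2, 6)."""
    male = np.array([1.0, 0.0]).reshape(2, 1)
    age = (np.asarray(AGE_MIDPOINTS) - 40.0).reshape(1, _N_AGE)
    c = coefficients
    lp = (c.get(outcome, "intercept") + c.get(outcome, "male") * male
          + c.get(outcome, "age_per_year") * age)
    return expit(lp)


@dataclass(frozen=True)
class TransitionProbabilities:
    """Precomputed annual probabilities (constant over a horizon run).

    Risk-factor values only change once, when an intervention shift is
    applied before the run, so every annual probability is fixed for the
    whole horizon and can be computed once.
    """

    no_cvd: dict[str, np.ndarray]     # outcome -> full cell-shape array
    post: dict[str, np.ndarray]       # outcome -> (2, 6)
    diabetes_adjusted: np.ndarray     # (2,6,3,3,3,3,3) probability, dm-free cells

    @classmethod
    def from_state(cls, state: ModelState,
                   coefficients: RiskFunctionCoefficients
                   ) -> "TransitionProbabilities":
        no_cvd = {o: _no_cvd_probability_array(state, coefficients, o)
                  for o in NO_CVD_OUTCOMES}
        post = {o: _post_cvd_probability_array(coefficients, o)
                for o in POST_CVD_OUTCOMES}
        naive_sum = (no_cvd["incident_chd"] + no_cvd["incident_stroke"]
                     + no_cvd["non_cvd_death"])
        if (naive_sum > 1).any():
            logger.warning(
                "naive annual probability sum exceeds 1 in %d cells; "
                "competing-risk hazard normalization applies",
                int((naive_sum > 1).sum()))
        # incident diabetes: hazard-scale the non-diabetic slice by the
        # stratum multiplier (RR semantics preserved for small p)
        p_dm = no_cvd["incident_diabetes"][:, :, :, :, :, :, 0, :]
        h_dm = -np.log1p(-p_dm)
        mult = state.diabetes_hazard_multiplier[:, :, None, None, None, None, None]
        diabetes_adjusted = -np.expm1(-mult * h_dm)
        return cls(no_cvd=no_cvd, post=post,
                   diabetes_adjusted=diabetes_adjusted)


# ---------------------------------------------------------------------------
# annual cycle


def _age_and_exit(arr: np.ndarray, age_axis: int = 1
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Promote 1/10 of each decade; return (aged array, exits at 95)."""
    moved = AGING_FRACTION * arr
    aged = arr - moved
    idx_to = [slice(None)] * arr.ndim
    idx_from = [slice(None)] * arr.ndim
    idx_to[age_axis] = slice(1, None)
    idx_from[age_axis] = slice(None, -1)
    aged[tuple(idx_to)] += moved[tuple(idx_from)]
    idx_last = [slice(None)] * arr.ndim
    idx_last[age_axis] = -1
    exits = moved[tuple(idx_last)]
    return aged, exits


def _step(
    state: ModelState,
    probs: TransitionProbabilities,
    entrants: np.ndarray,
    entrant_distribution: np.ndarray,
) -> tuple[ModelState, dict[str, np.ndarray]]:
    """One annual cycle given precomputed probabilities.

    Returns the new state and a report of event counts per (sex, age),
    plus entrants/exits vectors for conservation audits.
    """
    risk_axes = (2, 3, 4, 5, 6, 7)
    count = state.no_cvd

    p_chd = probs.no_cvd["incident_chd"]
    p_str = probs.no_cvd["incident_stroke"]
    p_ncd = probs.no_cvd["non_cvd_death"]
    h_chd = -np.log1p(-p_chd)
    h_str = -np.log1p(-p_str)
    h_ncd = -np.log1p(-p_ncd)
    h_tot = h_chd + h_str + h_ncd
    p_any = -np.expm1(-h_tot)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(h_tot > 0, p_any / np.where(h_tot > 0, h_tot, 1.0), 0.0)
    ev_chd = count * h_chd * scale
    ev_str = count * h_str * scale
    d_ncd = count * h_ncd * scale
    survivors = count - ev_chd - ev_str - d_ncd

    # incident diabetes among event-free survivors of non-diabetic cells
    flips = survivors[:, :, :, :, :, :, 0, :] * probs.diabetes_adjusted
    survivors = survivors.copy()
    survivors[:, :, :, :, :, :, 0, :] -= flips
    survivors[:, :, :, :, :, :, 1, :] += flips

    # prior-CVD pools: competing CVD / non-CVD death, recurrent events
    def pool_flows(pool, p_event, p_cvd_death, p_ncd_death):
        hc = -np.log1p(-p_cvd_death)
        hn = -np.log1p(-p_ncd_death)
        ht = hc + hn
        pa = -np.expm1(-ht)
        with np.errstate(invalid="ignore", divide="ignore"):
            sc = np.where(ht > 0, pa / np.where(ht > 0, ht, 1.0), 0.0)
        d_cvd = pool * hc * sc
        d_non = pool * hn * sc
        events = pool * p_event
        return pool - d_cvd - d_non, events, d_cvd, d_non

    chd_pool, rec_mi, chd_cvd_d, chd_ncd_d = pool_flows(
        state.prior_chd, probs.post["post_chd_event"],
        probs.post["post_chd_cvd_death"], probs.post["post_chd_non_cvd_death"])
    str_pool, rec_str, str_cvd_d, str_ncd_d = pool_flows(
        state.prior_stroke, probs.post["post_stroke_event"],
        probs.post["post_stroke_cvd_death"],
        probs.post["post_stroke_non_cvd_death"])

    # incident-event survivors join the prior pools (no acute case fatality;
    # CVD death acts through the prior-pool rates from the next cycle on)
    chd_pool = chd_pool + ev_chd.sum(axis=risk_axes)
    str_pool = str_pool + ev_str.sum(axis=risk_axes)

    # aging and exits at 95, then entrants at 35
    no_cvd_aged, no_cvd_exits = _age_and_exit(survivors)
    chd_aged, chd_exits = _age_and_exit(chd_pool)
    str_aged, str_exits = _age_and_exit(str_pool)
    no_cvd_aged[:, 0] += entrants[:, None, None, None, None, None, None] \
        * entrant_distribution

    new_state = replace(
        state, no_cvd=no_cvd_aged, prior_chd=chd_aged, prior_stroke=str_aged)

    cvd_deaths = chd_cvd_d + str_cvd_d
    non_cvd_deaths = (d_ncd.sum(axis=risk_axes) + chd_ncd_d + str_ncd_d)
    report = {
        "diabetes": flips.sum(axis=(2, 3, 4, 5, 6)),
        "mi": ev_chd.sum(axis=risk_axes) + rec_mi,
        "stroke": ev_str.sum(axis=risk_axes) + rec_str,
        "cvd_deaths": cvd_deaths,
        "non_cvd_deaths": non_cvd_deaths,
        "total_deaths": cvd_deaths + non_cvd_deaths,
        "entrants": entrants.copy(),
        "exits_95": (no_cvd_exits.sum(axis=tuple(range(1, no_cvd_exits.ndim)))
                     + chd_exits + str_exits),
    }
    return new_state, report


def advance_one_year(
    state: ModelState,
    coefficients: RiskFunctionCoefficients,
    demography: DemographyTable,
    year_index: int,
    entrant_distribution: np.ndarray | None = None,
) -> tuple[ModelState, dict[str, np.ndarray]]:
    """Run one annual cycle; see module docstring for the update order.

    ``entrant_distribution`` is the joint risk-factor distribution given to
    new 35-year-olds, shape (2, 3, 3, 3, 3, 2, 3) summing to 1 per sex; by
    default entrants inherit the age-35-44 mix implied by the current
    CVD-free pool (falling back to uniform when that stratum is empty).
    """
    state.validate()
    if entrant_distribution is None:
        base = state.no_cvd[:, 0]
        totals = base.sum(axis=tuple(range(1, base.ndim)), keepdims=True)
        uniform = np.full_like(base, 1.0 / base[0].size)
        with np.errstate(invalid="ignore", divide="ignore"):
            entrant_distribution = np.where(totals > 0, base / np.where(
                totals > 0, totals, 1.0), uniform)
    probs = TransitionProbabilities.from_state(state, coefficients)
    entrants = demography.entrants_for(year_index)
    return _step(state, probs, entrants, entrant_distribution)


# ---------------------------------------------------------------------------
# ledger and horizon


@dataclass(frozen=True)
class OutcomeLedger:
    """Annual event counts by year x sex x age group, plus audit fields.

    ``annual[outcome]`` has shape (T, 2, 6).  ``population`` has shape
    (T+1, 2, 6): start-of-year persons, all pools combined, with the final
    entry the end-of-horizon population.
    """

    start_year: int
    annual: dict[str, np.ndarray]
    population: np.ndarray
    entrants: np.ndarray  # (T, 2)
    exits_95: np.ndarray  # (T, 2)

    @property
    def years(self) -> list[int]:
        return [self.start_year + t
                for t in range(next(iter(self.annual.values())).shape[0])]

    def cumulative(self, outcome: str, by_stratum: bool = False):
        """Cumulative events over the horizon, total or per (sex, age)."""
        arr = self.annual[outcome].sum(axis=0)
        return arr if by_stratum else float(arr.sum())

    def cumulative_by_year(self, outcome: str) -> np.ndarray:
        return self.annual[outcome].sum(axis=(1, 2)).cumsum()

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: year, sex, age_group, outcome, count."""
        rows = []
        for outcome in REPORTED_OUTCOMES:
            arr = self.annual[outcome]
            for t in range(arr.shape[0]):
                for s, sex in enumerate(SEXES):
                    for a, group in enumerate(AGE_GROUPS):
                        rows.append({
                            "year": self.start_year + t, "sex": sex,
                            "age_group": group, "outcome": outcome,
                            "count": arr[t, s, a]})
        return pd.DataFrame(rows)

    def totals_frame(self) -> pd.DataFrame:
        """Cumulative totals per outcome, prevented-case table row order."""
        return pd.DataFrame(
            {"outcome": list(REPORTED_OUTCOMES),
             "cumulative": [self.cumulative(o) for o in REPORTED_OUTCOMES]})


def run_horizon(
    initial_state: ModelState,
    coefficients: RiskFunctionCoefficients,
    demography: DemographyTable,
    marginals: RiskFactorMarginals | None = None,
    horizon_years: int | None = None,
    start_year: int | None = None,
) -> OutcomeLedger:
    """Run the engine over the horizon and return the outcome ledger.

    Entrants receive the 35-44 joint risk-factor distribution from
    ``marginals`` when given (the documented behavior for full runs);
    otherwise the current-state mix, as in ``advance_one_year``.
    """
    if horizon_years is None:
        horizon_years = demography.horizon_years
    if horizon_years < 1:
        raise ValidationError("horizon must be >= 1 year")
    if start_year is None:
        start_year = demography.start_year
    entrant_distribution = None
    if marginals is not None:
        joint = np.stack([marginals.joint(s, 0) for s in range(2)])
        entrant_distribution = joint

    state = initial_state.copy()
    state.validate()
    probs = TransitionProbabilities.from_state(state, coefficients)
    annual = {o: np.zeros((horizon_years, 2, _N_AGE)) for o in REPORTED_OUTCOMES}
    population = np.zeros((horizon_years + 1, 2, _N_AGE))
    entrants = np.zeros((horizon_years, 2))
    exits = np.zeros((horizon_years, 2))
    for t in range(horizon_years):
        population[t] = state.population_by_stratum()
        if entrant_distribution is None:
            base = state.no_cvd[:, 0]
            totals = base.sum(axis=tuple(range(1, base.ndim)), keepdims=True)
            uniform = np.full_like(base, 1.0 / base[0].size)
            with np.errstate(invalid="ignore", divide="ignore"):
                dist = np.where(totals > 0,
                                base / np.where(totals > 0, totals, 1.0),
                                uniform)
        else:
            dist = entrant_distribution
        state, report = _step(state, probs, demography.entrants_for(t), dist)
        for o in REPORTED_OUTCOMES:
            annual[o][t] = report[o]
        entrants[t] = report["entrants"]
        exits[t] = report["exits_95"]
    population[horizon_years] = state.population_by_stratum()
    return OutcomeLedger(start_year=start_year, annual=annual,
                         population=population, entrants=entrants,
                         exits_95=exits)
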