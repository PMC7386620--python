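# Methods

## Model structure and assumptions

`ssbsim` is a deterministic, cell-based state-transition (Markov) cohort
model with annual cycles. The simulated population covers ages 35–94,
split by sex and six age decades. CVD-free persons are stratified by six
categorical cardiovascular risk factors (SBP, LDL, HDL, smoking, diabetes,
BMI — 486 combinations per sex × age stratum); persons with prior CHD or
prior stroke are tracked in separate pools stratified by sex × age only,
with no further risk-factor detail. Counts are nonnegative reals
(expected-value accounting), not sampled individuals: the model is a
compartmental cohort simulation, so all flows are linear in the cell
counts and the whole annual update of a fixed-probability population is a
transition matrix. The test suite uses exactly this property as an
independent oracle on toy populations.

Assumptions worth stating explicitly:

- **Risk-factor independence.** The joint occupancy of the 486 cells is
  the product of the categorical marginals within sex × age. Real risk
  factors are correlated (e.g., BMI with SBP and diabetes); no public
  joint distribution was available to the generator, and independence is
  reproducible and sufficient for property testing. Correlation would
  change absolute event counts but not the machinery.
- **Constant parameters.** All probabilities and effect sizes are held
  constant over the horizon, varying only with age; there are no secular
  trends in risk factors or treatment.
- **Aging by decade mixing.** One tenth of every decade cell is promoted
  per year (uniform age distribution within decades), 1/10 of the oldest
  decade exits at 95, and new 35-year-olds enter the CVD-free pool with
  the 35–44 joint risk-factor distribution.
- **Competing risks.** Within a cycle, incident CHD, incident stroke and
  non-CVD death compete on the hazard scale: `h = −ln(1−p)` per outcome,
  total event probability `1 − exp(−Σh)`, allocated proportionally to
  hazards. A warning is logged if naive probabilities ever sum above 1.
- **Event ordering.** Risks are evaluated on the start-of-year state.
  Incident diabetes applies to event-free survivors of non-diabetic cells
  (a diagnosis in the same year as a first CVD event or death is not
  counted) and changes risk functions from the next cycle onward.
- **No acute case fatality.** Survival of the incident event year is
  implicit: incident-event counts move to the prior-CVD pools, whose
  recurrent-event, CVD-death and non-CVD-death rates generate all CVD
  mortality. With the default rates, the first prior-CVD year carries a
  realistic post-event mortality load; a model needing explicit 28-day
  case fatality would add a thinning factor on the incident flows.
- **Prior-CVD recurrence.** Each pool has a single state per event type;
  recurrent events are counted as events but do not move persons.

## Risk functions

Annual probabilities are logistic. For CVD-free cells the linear predictor
is centered at a reference of women, age 40, SBP 120 mmHg, BMI 25 kg/m²,
first category of each categorical factor, no diabetes:

```
logit p = b0 + b_male·male + b_age·(age − 40) + b_sbp·(SBP − 120)
        + b_bmi·(BMI − 25) + b_ldl[cat] + b_hdl[cat] + b_smoke[cat]
        + b_dm·diabetic
```

Prior-CVD rates use intercept, sex and age terms only. The shipped
coefficient values are **synthetic defaults**: the source coefficient
tables for this class of model are not public, so plausible values were
chosen (annual incident CHD ≈ 0.2–3% rising with age, stroke lower,
incident diabetes ≈ 0.5–1%, Gompertz-like non-CVD mortality) and the
intercepts calibrated so the 10-year base-case totals land at the scale of
published national projections for Argentina (≈ 0.78M incident diabetes,
0.49M MI, 0.73M stroke, 0.64M CVD deaths, 3.3M total deaths for a 15.5M
population aged 35+). Every value, and its 95% CI used by the sensitivity
analysis, is overridable through the YAML config. Default CI half-widths
are 0.08 on intercepts and 10% of the value elsewhere — deliberately
modest, since in the paired design the coefficient draws shift base and
intervention together and mostly scale the prevented counts.

## Synthetic inputs (what they emulate, and what they do not)

The generator produces, from one configuration mapping:

- **Demography**: 15.55M persons 35–94 in 2015 (7.48M men, 8.07M women,
  declining with age), with 655k new 35-year-olds per year — the scale of
  Argentina's census projections. The projection table applies only
  inflow/aging bookkeeping; mortality belongs to the engine.
- **Risk-factor marginals**: hypertension, cholesterol, smoking, diabetes
  (≈ 10% overall, rising with age) and BMI categories shaped like national
  risk-factor-survey prevalences, plus per-category representative
  continuous values (SBP 120/135/150 mmHg; BMI 23/27.5/33 kg/m² —
  category midpoints, conventional values for the open-ended categories)
  and mean heights by sex × age.
- **Consumption profiles** in 12-oz (355 ml) servings/day, anchored at
  women 35–44 and scaled by sex × age factors that decline with age, with
  the 75+ groups set equal to 65–74. The **high** anchor is 269.6/355 ≈
  0.759 servings/day, the sales-corrected estimate for women 35–44 (the
  `derive_high_estimate_anchor` operation implements the full chain:
  total soda volume × regular-soda sales fraction (87.1%) × sales ratio ÷
  population ratio ÷ 355). The **low** anchor, 0.45 servings/day, is
  illustrative of self-reported survey intake; the per-stratum survey
  values are not published, so this profile is a stand-in, not a fit.
- **Prior-CVD prevalences** by sex × age, rising with age.

Because the inputs are synthetic, passing tests demonstrate the
*machinery* — conservation, oracle equivalence, monotonicity, pairing,
reproducibility — and the *relative* structure of results (dose response,
compensation response, age/sex gradients). Absolute prevented counts are
only as good as the synthetic inputs and should not be quoted as national
estimates.

## Intervention pathways

A scenario is (reduction fraction, compensation fraction, consumption
estimate). Servings change by `Δs = −r · baseline` per stratum. Effects,
all applied once in year 1 and held constant:

- direct SBP: 0.78 (men) / 0.61 (women) mmHg per serving/day;
- direct diabetes: RR 1.19 per serving/day;
- caloric: 150 kcal/serving, compensation fraction `c` of removed calories
  is replaced; exactly one year of daily imbalance accumulates into a
  permanent weight change at 3,500 kcal = 1 lb (0.45359237 kg). This
  one-year-accumulation choice matches the one-time application of all
  changes; a cumulative weight trajectory is out of scope.
- BMI-mediated SBP: 1.43 / 1.24 mmHg per kg/m² (men / women);
- BMI-mediated diabetes: RR per kg/m² anchored at 1.17 for ages 55–64.
  Only the anchor is published with the qualitative note that the RR
  declines with age, so the age profile is log-linear through the anchor
  with a configurable slope (default −0.04 per decade).

Direct and BMI-mediated diabetes effects compose multiplicatively on the
RR scale (no combination rule is published; multiplicative composition is
the standard assumption for independent RRs) and apply to annual
probabilities by hazard scaling, `p' = 1 − exp(−m·(−ln(1−p)))`, which
preserves RR semantics at small probabilities; the alternative
`1 − (1−p)^m` differs negligibly at modeled incidence levels.

The shift moves each stratum's representative SBP/BMI values (clamped to
physiologic bounds, SBP 80–250 mmHg, BMI 12–60 kg/m², with a logged
warning) and attaches the diabetes hazard multiplier; person counts are
untouched, and display category labels are recomputed from the shifted
continuous values. Note that shifted BMI also enters the CHD/stroke/death
risk functions directly through their BMI coefficients — the BMI pathway
is therefore only fully closed at 100% compensation.

A tax maps to a reduction either one-to-one (soda price elasticity is
close to −1, so a 10% or 20% tax is taken as a 10% or 20% reduction) or
through an explicit elasticity (`min(1, |ε|·tax)`).

## Scenarios and uncertainty

The default grid crosses {10%, 20%} × {0%, 39%, 100% compensation} ×
{low, high consumption} (12 scenarios), optionally plus 40% × 39%. One
base-case ledger is computed per consumption-estimate label and reused
bit-identically (the base case does not depend on the estimate at all;
the per-label cache simply mirrors the grid bookkeeping). Scenario runs
are fully deterministic.

The Monte Carlo varies, by default, the six effect sizes and every
non-degenerate risk-function coefficient. Draws are standard normals
scaled to each parameter's 95% CI, `sd = (hi − lo)/(2 × 1.959964)`;
relative risks are always drawn log-normally, and additive parameters
whose CI is markedly asymmetric (half-width difference > 5% of the width)
and positive — e.g. the women's direct SBP effect, 0.61 (0.27–1.48) — are
also drawn on the log scale, where their CI is approximately symmetric. A
`strict_normal` mode forces plain normal scaling for sensitivity. Within
an iteration the same draw drives the base and every intervention run;
prevented cases are differences of paired runs, and 95% UIs are empirical
2.5th/97.5th percentiles (linear interpolation) over iterations. Failed
iterations are logged and excluded; more than 1% failures aborts.
Everything is reproducible bit-for-bit from the seed.

## Reporting conventions

Counts are displayed to the nearest 100 at or above 1,000 and to the
nearest 50 below (half-up), with thousands separators; percent changes are
computed from unrounded counts and rounded half-up to one decimal (two for
very small percentages). Unrounded values are always written alongside
display strings, and CSVs are written with round-trip float formatting
(re-read with pandas' `float_precision="round_trip"` to recover identical
doubles). An undefined percent (zero base) renders as an em dash.

## Problem sizes and numerical choices

Default runs simulate the full 5,832-cell no-CVD array plus 24 prior-CVD
pools over 10 years (~15 ms per run); the shipped analyses use 1,000
Monte Carlo iterations, and the test suite uses 200 for the
reproducibility check and a 1,000-fold downscaled population for Monte
Carlo unit tests — the model is linear in counts, so downscaling changes
nothing but scale. Conservation (population t+1 = population t + entrants
− deaths − exits at 95) holds to 1e-9 relative each cycle; marginals are
renormalized at generation so categorical sums hold to 1e-9; degenerate
cells (zero hazard, zero population, empty entrant strata) take explicit
guarded branches.

## Known limitations

- Absolute counts inherit the synthetic inputs; only relative and
  structural results transfer.
- No correlation between risk factors, between draws of different
  parameters, or across time.
- Single-year-of-age resolution, treatment effects, tax revenue and
  cost-effectiveness are out of scope.
- The low-consumption profile and the age slope of the BMI–diabetes RR
  are the two inputs with no published numeric source; both are
  configuration values, chosen once and documented above.
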