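"""Engine tests: risk functions, annual cycle flows, and the ledger."""

import numpy as np
import pytest
from scipy.special import expit

import ssbsim
from ssbsim.constants import AGE_GROUPS, SEXES
from ssbsim.errors import ConfigurationError, ValidationError

from conftest import constant_probability_coefficients, make_toy_state


class TestAnnualRisk:
    def test_zero_coefficients_give_half(self, cfg):
        coefs = constant_probability_coefficients(cfg, {"incident_chd": 0.5})
        cell = ssbsim.PopulationCell(sex="women", age_group="35-44")
        assert ssbsim.annual_risk(cell, coefs, "incident_chd") \
            == pytest.approx(0.5, abs=1e-12)

    def test_intercept_only_logistic_closed_form(self, cfg):
        coefs = constant_probability_coefficients(cfg, {})
        coefs = coefs.with_updates({"coef.incident_chd.intercept": -9.2103})
        cell = ssbsim.PopulationCell(sex="women", age_group="35-44")
        p = ssbsim.annual_risk(cell, coefs, "incident_chd")
        assert p == pytest.approx(1 / (1 + np.exp(9.2103)), rel=1e-12)
        assert p == pytest.approx(1e-4, rel=1e-3)

    def test_sbp_monotonicity(self, inputs):
        lo = ssbsim.PopulationCell(sex="men", age_group="55-64", sbp=120)
        hi = ssbsim.PopulationCell(sex="men", age_group="55-64", sbp=150)
        assert (ssbsim.annual_risk(hi, inputs.coefficients, "incident_chd")
                > ssbsim.annual_risk(lo, inputs.coefficients, "incident_chd"))

    def test_unknown_outcome_rejected(self, inputs):
        cell = ssbsim.PopulationCell(sex="men", age_group="35-44")
        with pytest.raises(ConfigurationError):
            ssbsim.annual_risk(cell, inputs.coefficients, "levitation")

    def test_scalar_matches_vectorized_cell_array(self, inputs):
        """The scalar cell evaluation and the engine's vectorized array must
        agree on an arbitrary cell."""
        from ssbsim.model_core import _no_cvd_probability_array
        state = make_toy_state({(0, 2): 1.0})
        arr = _no_cvd_probability_array(state, inputs.coefficients,
                                        "incident_chd")
        cell = ssbsim.PopulationCell(
            sex="men", age_group="55-64",
            risk_profile={"ldl": "100-129.9", "smoking": "active",
                          "diabetes": "yes"},
            sbp=120.0, bmi=25.0)
        assert arr[0, 2, 0, 1, 0, 2, 1, 0] == pytest.approx(
            ssbsim.annual_risk(cell, inputs.coefficients, "incident_chd"),
            rel=1e-12)


class TestAdvanceOneYear:
    def test_zero_risk_leaves_only_aging(self, cfg):
        coefs = constant_probability_coefficients(cfg, {})
        state = make_toy_state({(0, 0): 1000.0})
        demo = ssbsim.generate_demography(
            {s: [0.0] * 6 for s in SEXES}, {s: 0.0 for s in SEXES}, 5)
        new, report = ssbsim.advance_one_year(state, coefs, demo, 0)
        assert new.no_cvd[0, 0, 0, 0, 0, 0, 0, 0] == pytest.approx(900.0)
        assert new.no_cvd[0, 1, 0, 0, 0, 0, 0, 0] == pytest.approx(100.0)
        for outcome in ("diabetes", "mi", "stroke", "total_deaths"):
            assert report[outcome].sum() == 0

    def test_single_cell_expected_flows(self, cfg):
        """1,000 persons at CHD risk 0.1 and no other risk: 100 events,
        900 stay CVD-free (before aging)."""
        coefs = constant_probability_coefficients(cfg, {"incident_chd": 0.1})
        state = make_toy_state({(0, 0): 1000.0})
        demo = ssbsim.generate_demography(
            {s: [0.0] * 6 for s in SEXES}, {s: 0.0 for s in SEXES}, 5)
        new, report = ssbsim.advance_one_year(state, coefs, demo, 0)
        assert report["mi"][0, 0] == pytest.approx(100.0, rel=1e-12)
        # survivors without CVD: 900, then 1/10 promoted
        assert new.no_cvd[0, 0, 0, 0, 0, 0, 0, 0] == pytest.approx(810.0)
        assert new.no_cvd[0, 1, 0, 0, 0, 0, 0, 0] == pytest.approx(90.0)
        # event survivors join the prior-CHD pool (aged likewise)
        assert new.prior_chd[0, 0] == pytest.approx(90.0)
        assert new.prior_chd[0, 1] == pytest.approx(10.0)

    def test_competing_risks_allocate_proportionally_to_hazards(self, cfg):
        p_chd, p_ncd = 0.08, 0.05
        coefs = constant_probability_coefficients(
            cfg, {"incident_chd": p_chd, "non_cvd_death": p_ncd})
        state = make_toy_state({(0, 0): 1000.0})
        demo = ssbsim.generate_demography(
            {s: [0.0] * 6 for s in SEXES}, {s: 0.0 for s in SEXES}, 5)
        _, report = ssbsim.advance_one_year(state, coefs, demo, 0)
        h_chd = -np.log1p(-p_chd)
        h_ncd = -np.log1p(-p_ncd)
        total = 1 - np.exp(-(h_chd + h_ncd))
        assert report["mi"][0, 0] == pytest.approx(
            1000 * total * h_chd / (h_chd + h_ncd), rel=1e-12)
        assert report["non_cvd_deaths"][0, 0] == pytest.approx(
            1000 * total * h_ncd / (h_chd + h_ncd), rel=1e-12)

    def test_negative_count_rejected(self, inputs):
        state = make_toy_state({(0, 0): 1.0})
        state.no_cvd[0, 1, 0, 0, 0, 0, 0, 0] = -1.0
        demo = ssbsim.generate_demography(
            {s: [0.0] * 6 for s in SEXES}, {s: 0.0 for s in SEXES}, 5)
        with pytest.raises(ValidationError):
            ssbsim.advance_one_year(state, inputs.coefficients, demo, 0)


def build_oracle_matrix(p_chd, p_ncd, p_cvd_death, p_post_ncd):
    """Hand-built 4-state annual transition matrix for the toy population.

    States: no-CVD 75-84, no-CVD 85-94, prior-CHD 75-84, prior-CHD 85-94.
    Transitions (documented engine order): competing incident CHD/non-CVD
    death via hazards, event survivors to prior-CHD, then 1/10 decade
    promotion with 85-94 exits.
    """
    h_chd = -np.log1p(-p_chd)
    h_ncd = -np.log1p(-p_ncd)
    h = h_chd + h_ncd
    p_any = 1 - np.exp(-h)
    frac_ev = p_any * h_chd / h
    frac_d = p_any * h_ncd / h
    stay = 1 - frac_ev - frac_d

    hc = -np.log1p(-p_cvd_death)
    hn = -np.log1p(-p_post_ncd)
    hp = hc + hn
    pool_stay = 1 - (1 - np.exp(-hp))

    M = np.zeros((4, 4))
    # no-CVD 75-84 -> stays (aged), to no-CVD 85-94, or to prior pools
    M[0, 0] = 0.9 * stay
    M[1, 0] = 0.1 * stay
    M[2, 0] = 0.9 * frac_ev
    M[3, 0] = 0.1 * frac_ev
    # no-CVD 85-94: 1/10 of survivors exits at 95
    M[1, 1] = 0.9 * stay
    M[3, 1] = 0.9 * frac_ev
    # prior-CHD pools
    M[2, 2] = 0.9 * pool_stay
    M[3, 2] = 0.1 * pool_stay
    M[3, 3] = 0.9 * pool_stay
    return M


class TestMatrixOracle:
    P = dict(p_chd=0.08, p_ncd=0.05, p_cvd_death=0.10, p_post_ncd=0.04)

    def _setup(self, cfg):
        coefs = constant_probability_coefficients(cfg, {
            "incident_chd": self.P["p_chd"],
            "non_cvd_death": self.P["p_ncd"],
            "post_chd_cvd_death": self.P["p_cvd_death"],
            "post_chd_non_cvd_death": self.P["p_post_ncd"],
        })
        state = make_toy_state(
            counts_no_cvd={(0, 4): 1000.0, (0, 5): 500.0},
            prior_chd={(0, 4): 200.0, (0, 5): 100.0})
        demo = ssbsim.generate_demography(
            {s: [0.0] * 6 for s in SEXES}, {s: 0.0 for s in SEXES}, 10)
        return coefs, state, demo

    def _engine_vector(self, state):
        return np.array([
            state.no_cvd[0, 4, 0, 0, 0, 0, 0, 0],
            state.no_cvd[0, 5, 0, 0, 0, 0, 0, 0],
            state.prior_chd[0, 4],
            state.prior_chd[0, 5],
        ])

    def test_three_year_counts_match_matrix_power(self, cfg):
        coefs, state, demo = self._setup(cfg)
        M = build_oracle_matrix(**self.P)
        v = self._engine_vector(state)
        for t in range(3):
            state, _ = ssbsim.advance_one_year(state, coefs, demo, t)
        expected = np.linalg.matrix_power(M, 3) @ v
        assert np.allclose(self._engine_vector(state), expected, rtol=1e-9)

    def test_ten_year_ledger_deaths_match_matrix_oracle(self, cfg):
        """Cumulative deaths over 10 years equal the oracle's leak terms."""
        coefs, state, demo = self._setup(cfg)
        M = build_oracle_matrix(**self.P)
        v0 = self._engine_vector(state)

        h_chd = -np.log1p(-self.P["p_chd"])
        h_ncd = -np.log1p(-self.P["p_ncd"])
        h = h_chd + h_ncd
        frac_d = (1 - np.exp(-h)) * h_ncd / h
        hc = -np.log1p(-self.P["p_cvd_death"])
        hn = -np.log1p(-self.P["p_post_ncd"])
        pa = 1 - np.exp(-(hc + hn))
        death_row = np.array([frac_d, frac_d,
                              pa * hc / (hc + hn) + pa * hn / (hc + hn),
                              pa * hc / (hc + hn) + pa * hn / (hc + hn)])
        expected_deaths = 0.0
        v = v0.copy()
        for _ in range(10):
            expected_deaths += death_row @ v
            v = M @ v
        ledger = ssbsim.run_horizon(state, coefs, demo, horizon_years=10)
        assert ledger.cumulative("total_deaths") == pytest.approx(
            expected_deaths, rel=1e-9)
        assert np.allclose(np.linalg.matrix_power(M, 10) @ v0, v, rtol=1e-12)


class TestConservationAndLedger:
    def test_population_conservation_every_cycle(self, base_ledger):
        """pop(t+1) = pop(t) + entrants - deaths - exits at 95, each year."""
        led = base_ledger
        for t in range(10):
            expected = (led.population[t].sum() + led.entrants[t].sum()
                        - led.annual["total_deaths"][t].sum()
                        - led.exits_95[t].sum())
            got = led.population[t + 1].sum()
            assert abs(got - expected) <= 1e-9 * max(1.0, expected)

    def test_counts_stay_nonnegative(self, base_ledger):
        assert (base_ledger.population >= 0).all()
        for outcome, arr in base_ledger.annual.items():
            assert (arr >= 0).all(), outcome

    def test_total_deaths_decompose_exactly(self, base_ledger):
        assert np.array_equal(
            base_ledger.annual["total_deaths"],
            base_ledger.annual["cvd_deaths"]
            + base_ledger.annual["non_cvd_deaths"])

    def test_cumulative_counts_nondecreasing(self, base_ledger):
        for outcome in ("diabetes", "mi", "stroke", "total_deaths"):
            cum = base_ledger.cumulative_by_year(outcome)
            assert np.all(np.diff(cum) >= 0)

    def test_one_year_horizon_equals_single_annual_report(self, inputs):
        state = ssbsim.build_initial_state(inputs)
        ledger = ssbsim.run_horizon(state, inputs.coefficients,
                                    inputs.demography,
                                    marginals=inputs.marginals,
                                    horizon_years=1)
        _, report = ssbsim.advance_one_year(
            state, inputs.coefficients, inputs.demography, 0,
            entrant_distribution=np.stack(
                [inputs.marginals.joint(s, 0) for s in range(2)]))
        for outcome in ("diabetes", "mi", "stroke", "total_deaths"):
            assert np.allclose(ledger.annual[outcome][0], report[outcome],
                               rtol=1e-12)

    def test_empty_population_stays_empty(self, cfg, inputs):
        state = make_toy_state({})
        demo = ssbsim.generate_demography(
            {s: [0.0] * 6 for s in SEXES}, {s: 0.0 for s in SEXES}, 10)
        ledger = ssbsim.run_horizon(state, inputs.coefficients, demo)
        assert ledger.population.sum() == 0
        for arr in ledger.annual.values():
            assert arr.sum() == 0

    def test_identical_inputs_give_bit_identical_ledgers(self, inputs):
        state = ssbsim.build_initial_state(inputs)
        a = ssbsim.run_horizon(state, inputs.coefficients, inputs.demography,
                               marginals=inputs.marginals)
        b = ssbsim.run_horizon(state, inputs.coefficients, inputs.demography,
                               marginals=inputs.marginals)
        for outcome in a.annual:
            assert np.array_equal(a.annual[outcome], b.annual[outcome])
        assert np.array_equal(a.population, b.population)

    def test_ledger_tidy_frame_shape(self, base_ledger):
        frame = base_ledger.to_frame()
        assert set(frame.columns) == {"year", "sex", "age_group", "outcome",
                                      "count"}
        assert len(frame) == 6 * 10 * len(SEXES) * len(AGE_GROUPS)


class TestInitialState:
    def test_pools_partition_base_population(self, inputs):
        state = ssbsim.build_initial_state(inputs)
        total = state.total_population()
        assert total == pytest.approx(inputs.demography.base_counts.sum(),
                                      rel=1e-12)
        # prior pools match prevalence x counts
        expected_chd = (inputs.demography.base_counts
                        * inputs.prior_chd_prevalence)
        assert np.allclose(state.prior_chd, expected_chd, rtol=1e-12)

    def test_mortality_rises_with_age_in_default_engine(self, inputs):
        state = ssbsim.build_initial_state(inputs)
        from ssbsim.model_core import _post_cvd_probability_array
        p = _post_cvd_probability_array(inputs.coefficients,
                                        "post_chd_cvd_death")
        assert np.all(np.diff(p, axis=1) > 0)
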