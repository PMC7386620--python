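"""Unit tests for the synthetic input generators."""

import itertools

import numpy as np
import pytest

import ssbsim
from ssbsim.constants import AGE_GROUPS, RISK_FACTORS, SEXES, SERVING_ML
from ssbsim.errors import ConfigurationError, ValidationError


class TestDemography:
    def test_baseline_counts_pass_through(self):
        base = {s: [100_000.0] * 6 for s in SEXES}
        table = ssbsim.generate_demography(base, {s: 10_000 for s in SEXES},
                                           horizon_years=10)
        year0 = table.frame[table.frame.year == table.start_year]
        assert len(year0) == 12
        assert (year0["count"] == 100_000).all()
        assert table.frame.year.nunique() == 11

    def test_zero_base_zero_entrants_is_all_zero(self):
        table = ssbsim.generate_demography(
            {s: [0.0] * 6 for s in SEXES}, {s: 0.0 for s in SEXES}, 5)
        assert (table.frame["count"] == 0).all()

    def test_inflow_bookkeeping_matches_spreadsheet_ledger(self):
        """Ten years of 1/10 decade promotion, 95 exits and entrants must
        equal an explicit year-by-year ledger computed independently."""
        base = {s: [100_000.0] * 6 for s in SEXES}
        entrants = {"men": 10_000.0, "women": 12_000.0}
        table = ssbsim.generate_demography(base, entrants, 10)

        counts = np.full((2, 6), 100_000.0)
        ent = np.array([10_000.0, 12_000.0])
        for _ in range(10):
            promoted = 0.1 * counts
            counts = counts - promoted
            counts[:, 1:] += promoted[:, :-1]
            counts[:, 0] += ent
        final = table.frame[table.frame.year == table.start_year + 10]
        for s, sex in enumerate(SEXES):
            got = final[final.sex == sex].sort_values("age_group")["count"]
            assert np.allclose(got.to_numpy(), counts[s], rtol=1e-12)

    def test_missing_stratum_names_it(self):
        with pytest.raises(ConfigurationError, match="women"):
            ssbsim.generate_demography({"men": [1.0] * 6},
                                       {s: 0.0 for s in SEXES}, 5)

    def test_negative_counts_rejected(self):
        base = {"men": [1.0] * 6, "women": [-1.0] * 6}
        with pytest.raises(ValidationError):
            ssbsim.generate_demography(base, {s: 0.0 for s in SEXES}, 5)


class TestMarginals:
    def test_configured_probabilities_pass_through(self, cfg):
        marg = ssbsim.generate_risk_factor_marginals(cfg["risk_factors"])
        expected = np.asarray(cfg["risk_factors"]["marginals"]["sbp"]["men"])
        assert np.allclose(marg.probs["sbp"][0], expected, atol=1e-12)

    def test_all_marginals_sum_to_one(self, inputs):
        for factor in RISK_FACTORS:
            sums = inputs.marginals.probs[factor].sum(axis=-1)
            assert np.all(np.abs(sums - 1.0) < 1e-9)

    def test_degenerate_marginal_gives_single_occupied_cell(self, cfg):
        import copy
        degenerate = copy.deepcopy(cfg["risk_factors"])
        for factor, cats in RISK_FACTORS.items():
            one_hot = [1.0] + [0.0] * (len(cats) - 1)
            for sex in SEXES:
                degenerate["marginals"][factor][sex] = [one_hot] * 6
        marg = ssbsim.generate_risk_factor_marginals(degenerate)
        joint = marg.joint(0, 0)
        assert joint[0, 0, 0, 0, 0, 0] == pytest.approx(1.0)
        assert np.count_nonzero(joint) == 1

    def test_joint_equals_product_on_exhaustive_enumeration(self, inputs):
        """All 486 cell occupancies equal the product of their marginals."""
        marg = inputs.marginals
        joint = marg.joint(1, 2)  # women, 55-64
        sizes = [len(c) for c in RISK_FACTORS.values()]
        assert joint.shape == tuple(sizes)
        n_checked = 0
        for combo in itertools.product(*[range(k) for k in sizes]):
            expected = 1.0
            for (factor, _), idx in zip(RISK_FACTORS.items(), combo):
                expected *= marg.probs[factor][1, 2, idx]
            assert joint[combo] == pytest.approx(expected, abs=1e-15)
            n_checked += 1
        assert n_checked == 486
        assert joint.sum() == pytest.approx(1.0, abs=1e-9)

    def test_bad_marginal_sum_rejected(self, cfg):
        import copy
        bad = copy.deepcopy(cfg["risk_factors"])
        bad["marginals"]["sbp"]["men"][0] = [0.5, 0.3, 0.1]
        with pytest.raises(ValidationError, match="sum"):
            ssbsim.generate_risk_factor_marginals(bad)


class TestConsumption:
    def test_uniform_scaling_returns_anchor_everywhere(self):
        anchor = 269.6 / SERVING_ML  # the sales-derived daily volume
        profile = ssbsim.generate_consumption_profiles(
            anchor, {s: [1.0] * 6 for s in SEXES})
        assert np.allclose(profile.servings, anchor)
        assert profile.servings[0, 0] == pytest.approx(0.7594, abs=5e-4)

    def test_zero_anchor_gives_zero_profile(self):
        profile = ssbsim.generate_consumption_profiles(
            0.0, {s: [1.0] * 6 for s in SEXES})
        assert (profile.servings == 0).all()

    def test_scaling_is_multiplicative(self):
        scaling = {"men": [1.5, 1, 1, 1, 1, 1], "women": [1.0] * 6}
        profile = ssbsim.generate_consumption_profiles(0.5, scaling)
        assert profile.for_stratum("men", "35-44") == pytest.approx(0.75)
        assert profile.for_stratum("women", "35-44") == pytest.approx(0.5)

    def test_75_plus_equals_65_74(self, inputs):
        for profile in inputs.consumption.values():
            assert np.array_equal(profile.servings[:, 4], profile.servings[:, 3])
            assert np.array_equal(profile.servings[:, 5], profile.servings[:, 3])

    def test_75_plus_rule_overrides_configured_scaling(self):
        scaling = {"men": [1, 1, 1, 0.5, 0.9, 0.2], "women": [1.0] * 6}
        profile = ssbsim.generate_consumption_profiles(1.0, scaling)
        assert profile.for_stratum("men", "75-84") == pytest.approx(0.5)
        assert profile.for_stratum("men", "85-94") == pytest.approx(0.5)

    def test_high_at_least_low_in_defaults(self, inputs):
        assert np.all(inputs.consumption["high"].servings
                      >= inputs.consumption["low"].servings)

    def test_negative_scaling_rejected(self):
        with pytest.raises(ValidationError):
            ssbsim.generate_consumption_profiles(
                1.0, {"men": [-1.0] * 6, "women": [1.0] * 6})


class TestHighEstimateAnchor:
    def test_plain_volume_conversion(self):
        assert ssbsim.derive_high_estimate_anchor(100, 1.0, 1.0, 1.0) \
            == pytest.approx(100 / 355, rel=1e-12)

    def test_regular_soda_fraction_scales_linearly(self):
        x = 310.0
        assert ssbsim.derive_high_estimate_anchor(x, 0.871, 1.0, 1.0) \
            == pytest.approx(0.871 * x / 355, rel=1e-12)

    def test_full_scaling_chain(self):
        got = ssbsim.derive_high_estimate_anchor(300.0, 0.871, 1.4, 1.1)
        assert got == pytest.approx(300.0 * 0.871 * 1.4 / 1.1 / 355, rel=1e-12)

    @pytest.mark.parametrize("kwargs", [
        dict(total_soda_ml=0, regular_fraction=1, sales_ratio=1,
             population_ratio=1),
        dict(total_soda_ml=100, regular_fraction=0, sales_ratio=1,
             population_ratio=1),
        dict(total_soda_ml=100, regular_fraction=1, sales_ratio=1,
             population_ratio=0),
    ])
    def test_degenerate_inputs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            ssbsim.derive_high_estimate_anchor(**kwargs)


class TestDeterminismAndSerialization:
    def test_same_config_gives_identical_inputs(self, cfg):
        a = ssbsim.generate_inputs(cfg, seed=1)
        b = ssbsim.generate_inputs(cfg, seed=1)
        assert a.demography.frame.equals(b.demography.frame)
        for factor in RISK_FACTORS:
            assert np.array_equal(a.marginals.probs[factor],
                                  b.marginals.probs[factor])
        for label in ("low", "high"):
            assert np.array_equal(a.consumption[label].servings,
                                  b.consumption[label].servings)

    def test_csv_export_round_trips_consumption(self, inputs, tmp_path):
        import pandas as pd

        paths = ssbsim.write_inputs_csv(inputs, tmp_path)
        assert set(paths) == {"demography", "marginals", "consumption",
                              "coefficients"}
        back = pd.read_csv(paths["consumption"])
        low = back[(back.estimate == "low") & (back.sex == "women")
                   & (back.age_group == "35-44")]["servings_per_day"].iloc[0]
        assert low == inputs.consumption["low"].servings[1, 0]

    def test_coefficient_probabilities_increase_with_age(self, inputs, cfg):
        """Under the default synthetic coefficients, every outcome's annual
        probability is nondecreasing across age decades at fixed profile."""
        for outcome in ("incident_chd", "incident_stroke", "non_cvd_death",
                        "incident_diabetes"):
            probs = [
                ssbsim.annual_risk(
                    ssbsim.PopulationCell(sex="men", age_group=group),
                    inputs.coefficients, outcome)
                for group in AGE_GROUPS]
            assert np.all(np.diff(probs) > 0)
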