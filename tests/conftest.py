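import numpy as np
import pytest

import ssbsim


@pytest.fixture(scope="session")
def cfg():
    return ssbsim.default_config()


@pytest.fixture(scope="session")
def inputs(cfg):
    return ssbsim.generate_inputs(cfg)


@pytest.fixture(scope="session")
def effect_params(cfg):
    return ssbsim.EffectParameters.from_config(cfg["effects"])


@pytest.fixture(scope="session")
def grid_results(inputs, effect_params):
    """Full default grid (incl. the 40% extreme runs), shared across tests."""
    return ssbsim.run_grid(ssbsim.default_grid(include_extreme=True),
                           inputs, effect_params)


@pytest.fixture(scope="session")
def base_ledger(inputs, effect_params):
    return ssbsim.run_scenario(ssbsim.base_scenario("low"), inputs,
                               effect_params)


def make_toy_state(counts_no_cvd=None, prior_chd=None, prior_stroke=None,
                   sbp=120.0, bmi=25.0):
    """A mostly-empty state with a few hand-placed cells.

    ``counts_no_cvd`` maps (sex_idx, age_idx) -> count placed in the
    all-first-category risk cell of that stratum.
    """
    no_cvd = np.zeros((2, 6, 3, 3, 3, 3, 2, 3))
    for (s, a), c in (counts_no_cvd or {}).items():
        no_cvd[s, a, 0, 0, 0, 0, 0, 0] = c
    pc = np.zeros((2, 6))
    for (s, a), c in (prior_chd or {}).items():
        pc[s, a] = c
    ps = np.zeros((2, 6))
    for (s, a), c in (prior_stroke or {}).items():
        ps[s, a] = c
    return ssbsim.ModelState(
        no_cvd=no_cvd, prior_chd=pc, prior_stroke=ps,
        sbp_values=np.full((2, 6, 3), sbp),
        bmi_values=np.full((2, 6, 3), bmi))


def constant_probability_coefficients(cfg, probabilities):
    """Coefficients in which each outcome has a fixed probability.

    ``probabilities`` maps outcome -> annual probability; all slope terms
    are zeroed so every cell shares the outcome's probability.
    """
    from scipy.special import logit

    coefs = {}
    for outcome, terms in cfg["coefficients"].items():
        new_terms = {}
        for term, entry in terms.items():
            if isinstance(entry, list):
                new_terms[term] = [{"value": 0.0, "ci": [0.0, 0.0]}] * len(entry)
            else:
                new_terms[term] = {"value": 0.0, "ci": [0.0, 0.0]}
        p = probabilities.get(outcome, 0.0)
        b0 = float(logit(p)) if p > 0 else float("-inf")  # expit(-inf) == 0
        new_terms["intercept"] = {"value": b0, "ci": [b0, b0]}
        coefs[outcome] = new_terms
    return ssbsim.generate_risk_function_coefficients(coefs)


@pytest.fixture(scope="session")
def toy_inputs(cfg):
    """Small-population inputs for fast Monte Carlo runs (same structure)."""
    import copy

    small = copy.deepcopy(cfg)
    for sex in ("men", "women"):
        small["demography"]["base_counts"][sex] = [
            c / 1000 for c in small["demography"]["base_counts"][sex]]
        small["demography"]["entrants"][sex] /= 1000
    return ssbsim.generate_inputs(small)
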