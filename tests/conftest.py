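import numpy as np
import pytest

import heatexcess as hx


@pytest.fixture(scope="session")
def small_strong_cohort():
    """Reduced strong-effect cohort: 40 expected + 15 excess cases, 800 controls."""
    params = hx.strong_effect_scenario(
        n_controls=800, n_expected_cases=40, n_excess_cases=15, seed=42)
    cohort, truth = hx.generate_cohort(params)
    return cohort, truth


@pytest.fixture(scope="session")
def study_scale_cohort():
    """Study-scale synthetic cohort: 411 cases (114 excess), 11,632 controls."""
    params = hx.strong_effect_scenario(seed=7)
    cohort, truth = hx.generate_cohort(params)
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
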