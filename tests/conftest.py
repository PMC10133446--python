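import numpy as np
import pytest

import timbrecapture as tc


@pytest.fixture(scope="session")
def exp2_config():
    return tc.load_experiment("exp2")


@pytest.fixture(scope="session")
def exp2_plan(exp2_config):
    return tc.generate_plan(exp2_config, seed=7)


@pytest.fixture(scope="session")
def small_cohort(exp2_plan):
    """A quick 6-participant trial log on the 4-level brightness design."""
    pop = tc.PopulationSpec(mean=tc.ObserverParams(), mu_rt_sd_ms=100.0)
    return tc.simulate_cohort(exp2_plan, n_participants=6, population=pop, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
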