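import numpy as np
import pytest

from icie import ScenarioConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-per-group cohort with censoring and both IE strata populated."""
    cfg = ScenarioConfig(n_per_group=40, c_p=0.3, seed=101)
    return generate_cohort(cfg)
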