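import numpy as np
import pytest
from hypothesis import settings

from alcmr.derive import add_derived_columns
from alcmr.simulate import simulate_cohort, table2_preset

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def preset_cohort():
    """One full-size preset cohort with derived columns, shared read-only."""
    params = table2_preset(seed=11)
    return add_derived_columns(simulate_cohort(params))


@pytest.fixture(scope="session")
def small_cohort():
    """A small preset cohort for cheap smoke tests."""
    params = table2_preset(n_total=1500, seed=5)
    return add_derived_columns(simulate_cohort(params))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
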