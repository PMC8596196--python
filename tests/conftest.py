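import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from msdr.simulate import SimConfig, simulate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Model-fit warnings (degenerate folds on tiny data) are expected noise."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_cohort_tables():
    """One confounded null cohort at modest size, shared across tests."""
    config = SimConfig(n_patients=600, seed=42)
    return config, simulate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
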