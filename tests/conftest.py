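import warnings

import numpy as np
import pytest

from ablmap import SimParams, simulate_cohort
from ablmap.events import classify_cohort

warnings.filterwarnings("ignore", category=RuntimeWarning, message="Mean of empty slice")


@pytest.fixture(scope="session")
def small_params():
    return SimParams(n_mice=2, n_fov_per_mouse=2, neurons_per_fov=(110, 130), seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    """A small control cohort shared across read-only tests."""
    return simulate_cohort(small_params, cohort="control")


@pytest.fixture(scope="session")
def small_resp(small_cohort):
    return classify_cohort(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
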