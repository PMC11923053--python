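import numpy as np
import pytest

from coldcarb import ConditionRealization, find_steady_state, generate_study
from coldcarb.synthetic_data import BASE_PARAMETERS


@pytest.fixture(scope="session")
def base_params():
    return BASE_PARAMETERS


@pytest.fixture(scope="session")
def base_realization(base_params):
    ss = find_steady_state(base_params)
    return ConditionRealization("Col-0", 0, base_params, ss)


@pytest.fixture(scope="session")
def small_study():
    """3 genotypes × 2 days, 5 % observation noise."""
    return generate_study(n_genotypes=3, n_days=2, noise_cv=0.05, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
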