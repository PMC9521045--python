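import warnings

import numpy as np
import pytest

from lactecon.synthetic_data import SyntheticConfig, generate_population

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*convergence.*")


@pytest.fixture(scope="session")
def small_population():
    """A 10-herd, 6-year population shared by read-only tests."""
    config = SyntheticConfig(
        n_herds=10, years=(2008, 2013), herd_size_mean=10, rng_seed=7
    )
    return config, generate_population(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
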