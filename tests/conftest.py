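import numpy as np
import pytest

from zfhunt.synthetic import GroupConfig, default_configs

# reduced MCMC settings for unit tests (acceptance tests use the full
# contract of 3 chains x 2000 draws)
FAST_MCMC = dict(n_chains=2, n_draws=600, n_warmup=400)


@pytest.fixture
def lf_config() -> GroupConfig:
    return default_configs()["LF"]


@pytest.fixture
def configs():
    return default_configs()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
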