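import numpy as np
import pytest

from ribotempo import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config():
    return sd.SyntheticConfig(
        n_genes=30, length_range=(120, 250), cub_skew=2.5, seed=11
    )


@pytest.fixture(scope="session")
def small_orfeome(small_config):
    return sd.gen_orfeome(small_config)


@pytest.fixture(scope="session")
def small_tables(small_orfeome, small_config):
    return sd.gen_param_tables(small_orfeome, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
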