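import numpy as np
import pytest

from chemoflux import synthdata


@pytest.fixture(scope="session")
def default_series():
    return synthdata.generate_chemostat_series(seed=1)


@pytest.fixture(scope="session")
def noiseless_proteome(default_series):
    return synthdata.generate_proteome(default_series, cv_noise=0.0, seed=2)


@pytest.fixture(scope="session")
def toy_model():
    return synthdata.build_toy_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
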