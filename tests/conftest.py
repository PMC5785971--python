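import numpy as np
import pytest

from duplexsis import EpidemicParams, MeanFieldConfig, make_random_regular_multiplex


@pytest.fixture(scope="session")
def small_multiplex():
    """Random-regular multiplex small enough for per-test dynamics."""
    return make_random_regular_multiplex(200, 6, 10, seed=42)


@pytest.fixture
def default_params():
    return EpidemicParams(
        beta1=0.02, beta2=0.02, gamma1=0.08, gamma2=0.08, resource=0.2
    )


@pytest.fixture
def default_config(default_params):
    return MeanFieldConfig(params=default_params, k1=30, k2=30)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
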