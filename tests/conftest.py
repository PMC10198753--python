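import numpy as np
import pytest
from hypothesis import HealthCheck, settings as hyp_settings

from telerehab_cea import packaged_parameters

hyp_settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
hyp_settings.load_profile("ci")


@pytest.fixture(scope="session")
def packaged():
    return packaged_parameters()


@pytest.fixture()
def params(packaged):
    return packaged[0]


@pytest.fixture()
def settings(packaged):
    return packaged[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(20230520)
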