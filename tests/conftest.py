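import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    from circanap.protocol import ProtocolConfig

    return ProtocolConfig()


@pytest.fixture(scope="session")
def default_schedule(default_config):
    from circanap.protocol import generate_protocol

    return generate_protocol(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240622)
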