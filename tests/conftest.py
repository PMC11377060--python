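import numpy as np
import pytest

from beemb.protocol import StimulusProtocol
from beemb.synthetic import GeneratorConfig, make_profile_database


@pytest.fixture(scope="session")
def protocol():
    """Imaging-scale default protocol (127 Hz, 5 s ON, 20 trials)."""
    return StimulusProtocol()


@pytest.fixture(scope="session")
def fast_protocol():
    """Small, fast protocol for unit tests that only need the grid."""
    return StimulusProtocol(sampling_rate_hz=60.0, record_window_s=12.0)


@pytest.fixture(scope="session")
def conditioning_protocol():
    """Pre-stimulus coverage for the backward learning window."""
    return StimulusProtocol(pre_window_s=2.0, record_window_s=19.0)


@pytest.fixture(scope="session")
def gen_config():
    return GeneratorConfig(seed=123)


@pytest.fixture(scope="session")
def profile_db(gen_config, fast_protocol):
    return make_profile_database(gen_config, fast_protocol, n_per_group=6, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
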