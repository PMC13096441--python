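import numpy as np
import pytest

from twitchlab.config import AnalysisConfig
from twitchlab.pipeline import make_fixtures


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def fixture_session():
    """The bundled 15-min simulated session (4 neurons, 4 body parts)."""
    return make_fixtures(seed=3, duration=900.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
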