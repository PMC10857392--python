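import numpy as np
import pytest

from semgcal import GeneratorConfig, generate_database


@pytest.fixture(scope="session")
def small_db():
    """Compact database: 2 sessions x 2 gestures x 3 trials, default drift."""
    return generate_database(GeneratorConfig(n_sessions=2, n_gestures=2, n_trials=3, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
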