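import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import aftvlrr as a

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def std_data():
    """Standard noisy dataset: 3x30 cells, 200 genes, noise 0.1, dropout 0.3."""
    return a.standard_fixture()


@pytest.fixture(scope="session")
def clean_data():
    """Noise-free, dropout-free variant (exact low-rank signal)."""
    return a.clean_fixture()


@pytest.fixture(scope="session")
def std_preprocessed(std_data):
    X, labels = std_data
    return a.preprocess(X), labels


@pytest.fixture(scope="session")
def std_solution(std_preprocessed):
    """One default-parameter solver run on the standard dataset."""
    Xp, labels = std_preprocessed
    state, sim = a.fit_aftv_lrr(Xp.values)
    return Xp, labels, state, sim


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
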