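import numpy as np
import pytest

from pneumotex import ProfusionClassifier, SyntheticParams
from pneumotex.synthetic import generate_arrays


@pytest.fixture(scope="session")
def params64():
    """Generator parameters rescaled for 64-pixel tiles."""
    return SyntheticParams().scaled(64)


@pytest.fixture(scope="session")
def trained_small(params64):
    """A modestly trained classifier plus a held-out set, shared by the
    slower behavioural tests (ordinality, staging agreement)."""
    images, levels, _ = generate_arrays(40, params64, seed=11)
    X_train, y_train = images[:128], levels[:128]
    X_test, y_test = images[128:], levels[128:]
    est = ProfusionClassifier(epochs=12, learning_rate=1e-3, random_state=0)
    est.fit(X_train, y_train)
    return est, X_test, y_test


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
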