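import numpy as np
import pytest

from qscore3d import (
    FixtureSpec,
    QScoreParams,
    make_isolated_model,
    make_map,
    make_toy_model,
    model_q,
)


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_model()


@pytest.fixture(scope="session")
def isolated_model():
    return make_isolated_model(n_atoms=4, spacing=12.0)


@pytest.fixture(scope="session")
def params():
    return QScoreParams(rng_seed=7)


@pytest.fixture(scope="session")
def toy_map(toy_model):
    """Sharp (B=0), noise-free rendering of the toy model."""
    return make_map(toy_model, FixtureSpec())


@pytest.fixture(scope="session")
def toy_table(toy_model, toy_map, params):
    """Q-scores of the toy model against its own sharp rendering."""
    return model_q(toy_model, toy_map, params)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
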