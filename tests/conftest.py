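from pathlib import Path

import numpy as np
import pytest

from redqueen import Dominance, Regime, Strategy

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210898)


@pytest.fixture(params=list(Dominance), ids=lambda d: d.value)
def scheme(request) -> Dominance:
    return request.param


@pytest.fixture
def mild_regime() -> Regime:
    """A moderate-selection regime used for short dynamical checks."""
    return Regime(0.5, 0.7, 0.2, Dominance.ANTI_PHASE)


@pytest.fixture
def extreme_regime() -> Regime:
    """The extreme-selection example regime (high host optimum)."""
    return Regime(0.98, 0.995, 0.3, Dominance.ANTI_PHASE)


def random_state(rng: np.random.Generator):
    """A random valid population state (symmetric, normalized matrices)."""
    from redqueen import PopulationState

    h = rng.random((8, 8))
    h = h + h.T
    p = rng.random((4, 4))
    p = p + p.T
    return PopulationState(h / h.sum(), p / p.sum())


@pytest.fixture
def resident() -> Strategy:
    return Strategy.constant(0.2)
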