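import numpy as np
import pytest

from gsscox import GroupStructure, SurvivalOutcome, simulate_survival


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_outcome():
    """Three subjects, all events, distinct times."""
    return SurvivalOutcome(np.array([1.0, 2.0, 3.0]), np.array([1.0, 1.0, 1.0]))


def random_survival(rng, n, censor=0.3):
    time = rng.exponential(size=n) + 1e-3
    status = (rng.random(n) > censor).astype(float)
    if status.sum() == 0:
        status[0] = 1.0
    return SurvivalOutcome(time, status)


@pytest.fixture
def small_cox_data(rng):
    """n=40, p=3 design with genuine signal, ~30% censoring."""
    n, p = 40, 3
    X = rng.normal(size=(n, p))
    beta = np.array([0.8, -0.5, 0.0])
    y, _, _ = simulate_survival(X, beta, 7)
    return X, y, beta


@pytest.fixture
def grouped_data(rng):
    """n=150, p=30 with one signal-bearing group out of three."""
    n, p = 150, 30
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[[2, 5, 8]] = [1.0, -0.8, 0.9]
    y, _, _ = simulate_survival(X, beta, 11)
    gs = GroupStructure.from_spec(
        {"a": np.arange(0, 10), "b": np.arange(10, 20), "c": np.arange(20, 30)}, p
    )
    return X, y, beta, gs
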