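import numpy as np
import pytest

from grmsim import Condition, ItemBank, generate_population


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_bank():
    """A fixed 4-item, 5-category bank with spread locations."""
    a = np.array([0.8, 1.2, 1.8, 2.3])
    b = np.array(
        [
            [-1.5, -0.5, 0.5, 1.2],
            [-1.0, -0.2, 0.4, 1.5],
            [-1.8, -0.9, 0.1, 0.8],
            [-0.7, 0.0, 0.9, 1.9],
        ]
    )
    return ItemBank(a=a, b=b)


@pytest.fixture
def symmetric_item():
    """One item whose locations are symmetric about zero (K = 4)."""
    return ItemBank(a=np.array([1.0]), b=np.array([[-1.0, 0.0, 1.0]]))


@pytest.fixture(scope="session")
def tiny_population():
    """A small condition's population, shared across tests (n=200, J=4, K=3)."""
    cond = Condition(n=200, J=4, K=3, R=3, base_seed=7)
    return generate_population(cond)
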