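import numpy as np
import pandas as pd
import pytest

from pmnet import RoiSet, default_roiset


@pytest.fixture
def toy_roiset() -> RoiSet:
    """2 parietal + 3 premotor ROIs: 6 interlobar pairs."""
    return RoiSet(pd.DataFrame({
        "name": ["P1", "P2", "F1", "F2", "F3"],
        "lobe": ["parietal", "parietal", "premotor", "premotor", "premotor"],
        "subdomain": ["SPL", "IPL", "PMC", "PMC", "SMA"],
        "hemisphere": ["left"] * 5,
    }))


@pytest.fixture
def atlas() -> RoiSet:
    return default_roiset("left")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)


def random_symmetric_weights(rng: np.random.Generator, n: int,
                             density: float = 0.5) -> np.ndarray:
    """Random symmetric nonnegative weight matrix with zero diagonal."""
    upper = np.triu(rng.random((n, n)) * (rng.random((n, n)) < density), k=1)
    return upper + upper.T


def random_connected_weights(rng: np.random.Generator, n: int,
                             density: float = 0.5) -> np.ndarray:
    """Random connected weighted graph (spanning chain plus random edges)."""
    W = random_symmetric_weights(rng, n, density)
    order = rng.permutation(n)
    for a, b in zip(order, order[1:]):
        if W[a, b] == 0:
            W[a, b] = W[b, a] = 0.2 + 0.8 * rng.random()
    return W
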