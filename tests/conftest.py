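import numpy as np
import pytest

from connectopred import ConnectomeMatrix


def random_connected_weighted(rng: np.random.Generator, n: int, density: float = 0.5) -> np.ndarray:
    """Random connected weighted graph: a random spanning chain plus extra
    edges, continuous weights in (0.2, 1] so shortest paths are a.s. unique."""
    W = np.zeros((n, n))
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):
        W[a, b] = W[b, a] = rng.uniform(0.2, 1.0)
    iu = np.triu_indices(n, k=1)
    extra = rng.random(iu[0].size) < density
    for i, j in zip(iu[0][extra], iu[1][extra]):
        if W[i, j] == 0:
            W[i, j] = W[j, i] = rng.uniform(0.2, 1.0)
    return W


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def graph_factory():
    def make(seed: int, n: int, density: float = 0.5) -> ConnectomeMatrix:
        g = np.random.default_rng(seed)
        return ConnectomeMatrix(
            W=random_connected_weighted(g, n, density), modality="SC"
        )

    return make
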