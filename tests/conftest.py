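import numpy as np
import pytest

from constrainet import Network, SynthSpec, generate


@pytest.fixture(scope="session")
def synth_default():
    """Default-condition synthetic connectome (56 nodes) with ground truth."""
    return generate(SynthSpec())


@pytest.fixture(scope="session")
def synth_small():
    """Reduced synthetic connectome (32 nodes) for heavier per-sample work."""
    return generate(SynthSpec(n_areas_per_hemisphere=16, n_hubs=2, seed=0))


@pytest.fixture
def net22():
    return Network(weights=[[0.0, 2.0], [3.0, 0.0]])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def two_cliques(k: int = 4, w: float = 1.0) -> Network:
    """Two disconnected reciprocal k-cliques (2k nodes)."""
    n = 2 * k
    W = np.zeros((n, n))
    W[:k, :k] = w
    W[k:, k:] = w
    np.fill_diagonal(W, 0.0)
    return Network(weights=W)
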