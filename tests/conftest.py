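import numpy as np
import pytest

from batalign.io_formats import Network


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_network(n, p, rng, prefix="v"):
    """Erdős–Rényi network built directly (independent of the synthetic
    module), for oracle tests."""
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)
             if rng.uniform() < p]
    return Network([f"{prefix}{i}" for i in range(n)], edges)


def random_alignment(n1, n2, rng):
    return rng.choice(n2, size=n1, replace=False).astype(np.int64)


@pytest.fixture
def triangle():
    return Network(["a", "b", "c"], [(0, 1), (1, 2), (0, 2)])
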