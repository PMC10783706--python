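import numpy as np
import pytest

from spiralsilence.netgen import Graph, Population


@pytest.fixture
def rng():
    return np.random.default_rng(20240111)


@pytest.fixture
def triangle_graph():
    return Graph.from_edges(3, [(0, 1), (1, 2), (0, 2)])


def make_population(b, sigma, omega, is_hc=None, has_expressed=None):
    """Assemble a Population from plain lists (test helper)."""
    b = np.asarray(b, dtype=np.int8)
    n = b.shape[0]
    omega = np.asarray(omega, dtype=np.int8)
    if is_hc is None:
        is_hc = np.zeros(n, dtype=bool)
    if has_expressed is None:
        has_expressed = omega != 0
    return Population(
        b=b,
        sigma=np.asarray(sigma, dtype=np.float64),
        omega=omega,
        is_hc=np.asarray(is_hc, dtype=bool),
        has_expressed=np.asarray(has_expressed, dtype=bool),
    )
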