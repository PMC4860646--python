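import numpy as np
import pytest

from netparticles.graphs import Graph


@pytest.fixture
def triangle() -> Graph:
    return Graph.from_edges([(0, 1), (1, 2), (2, 0)])


@pytest.fixture
def path3() -> Graph:
    """Path 0-1, 0-2: nodes 1 and 2 are non-adjacent."""
    return Graph.from_edges([(0, 1), (0, 2)])


@pytest.fixture
def complete5() -> Graph:
    return Graph.from_edges([(i, j) for i in range(5) for j in range(i + 1, 5)])


def random_graph(n: int, p: float, seed: int) -> Graph:
    rng = np.random.default_rng(seed)
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p
    ]
    return Graph.from_edges(edges, nodes=range(n))
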