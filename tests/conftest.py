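import numpy as np
import pytest

from braingen import BrainGraph


def random_graph(n: int, p: float, seed: int) -> BrainGraph:
    """Erdős–Rényi-style random test graph with 1-based node ids."""
    rng = np.random.default_rng(seed)
    nodes = list(range(1, n + 1))
    edges = [
        (u, v)
        for i, u in enumerate(nodes)
        for v in nodes[i + 1:]
        if rng.random() < p
    ]
    return BrainGraph(nodes, edges)


@pytest.fixture
def triangle():
    return BrainGraph([1, 2, 3], [(1, 2), (2, 3), (1, 3)])


@pytest.fixture
def star5():
    """Hub 1 with five leaves."""
    return BrainGraph(range(1, 7), [(1, k) for k in range(2, 7)])


@pytest.fixture
def k4():
    nodes = [1, 2, 3, 4]
    return BrainGraph(nodes, [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]])


@pytest.fixture
def k5():
    nodes = [1, 2, 3, 4, 5]
    return BrainGraph(nodes, [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]])


@pytest.fixture
def path3():
    return BrainGraph([1, 2, 3], [(1, 2), (2, 3)])


@pytest.fixture
def mi_fixture():
    """Seven-node graph with varied degrees, triangles and open wedges."""
    return BrainGraph(
        range(1, 8),
        [(1, 2), (1, 3), (2, 3), (2, 4), (3, 4), (4, 5), (5, 6), (5, 7), (6, 7), (1, 5)],
    )


@pytest.fixture
def triangle_pendant():
    """Triangle {1,2,3} plus pendant node 4 attached to 1."""
    return BrainGraph([1, 2, 3, 4], [(1, 2), (2, 3), (1, 3), (1, 4)])
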