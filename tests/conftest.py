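import numpy as np
import pytest

from corrgraph import Graph


@pytest.fixture
def two_triangles_bridge():
    """Two triangles {a,b,c} and {d,e,f} joined by the bridge c-d."""
    g = Graph()
    for u, v in [("a", "b"), ("b", "c"), ("a", "c"),
                 ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")]:
        g.add_edge(u, v)
    return g


@pytest.fixture
def path5():
    g = Graph()
    for u, v in [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")]:
        g.add_edge(u, v)
    return g


def random_weighted_graph(rng: np.random.Generator, n_max: int = 12,
                          p: float | None = None) -> Graph:
    """Small random weighted graph for oracle comparisons."""
    n = int(rng.integers(2, n_max + 1))
    p = p if p is not None else float(rng.uniform(0.2, 0.7))
    g = Graph()
    names = [f"n{i:02d}" for i in range(n)]
    g.add_nodes(names)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(names[i], names[j], float(rng.uniform(0.05, 1.0)))
    return g
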