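import numpy as np
import pytest

from commdiff.graph import Graph, Partition
from commdiff.lfr import LFRParams, generate_lfr


@pytest.fixture
def two_triangles():
    g = Graph([("a", "b"), ("b", "c"), ("a", "c"),
               ("d", "e"), ("e", "f"), ("d", "f")])
    p = Partition(g, {"a": "x", "b": "x", "c": "x",
                      "d": "y", "e": "y", "f": "y"})
    return g, p


@pytest.fixture
def bridged_triangles():
    """Two triangles joined by a single bridge edge c-d."""
    g = Graph([("a", "b"), ("b", "c"), ("a", "c"),
               ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")])
    p = Partition(g, {"a": "x", "b": "x", "c": "x",
                      "d": "y", "e": "y", "f": "y"})
    return g, p


@pytest.fixture
def triangle():
    return Graph([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture(scope="session")
def lfr_strong():
    """One strong-community LFR instance shared across tests."""
    return generate_lfr(LFRParams(mu=0.05, seed=1))


def random_graph(n: int, p: float, rng: np.random.Generator) -> Graph:
    """Erdos-Renyi graph with all n nodes declared (isolates possible)."""
    labels = [f"v{i:03d}" for i in range(n)]
    edges = [
        (labels[i], labels[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return Graph(edges, nodes=labels)


def random_partition(graph: Graph, c: int, rng: np.random.Generator) -> Partition:
    memb = rng.integers(0, c, size=graph.N)
    # every community non-empty
    memb[rng.permutation(graph.N)[:c]] = np.arange(c)
    return Partition(
        graph, {lab: f"c{memb[i]}" for i, lab in enumerate(graph.labels)}
    )
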