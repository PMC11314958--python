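"""Shared fixtures: canonical toy graphs and small synthetic cohorts."""
import numpy as np
import pytest

from connectolesion import BinaryGraph, WeightedConnectome


def graph_from_edges(n, edges, labels=None):
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    labels = labels or tuple(f"n{i}" for i in range(n))
    return BinaryGraph(labels=labels, adjacency=a)


def random_graph(rng, n=None, p=None):
    n = n or int(rng.integers(4, 31))
    p = p if p is not None else rng.uniform(0.15, 0.7)
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    a = a + a.T
    return BinaryGraph(labels=tuple(f"n{i}" for i in range(n)), adjacency=a)


@pytest.fixture
def k4():
    return graph_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])


@pytest.fixture
def p3():
    return graph_from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def p4():
    return graph_from_edges(4, [(0, 1), (1, 2), (2, 3)])


@pytest.fixture
def star4():
    """Hub node 0 with three leaves."""
    return graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])


@pytest.fixture
def c5():
    return graph_from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)])


@pytest.fixture
def toy_weighted():
    """4-node weighted connectome with strictly ordered weights."""
    w = np.zeros((4, 4))
    for (i, j), v in {(0, 1): 5, (0, 2): 4, (0, 3): 3, (1, 2): 2, (1, 3): 1, (2, 3): 0.5}.items():
        w[i, j] = w[j, i] = v
    return WeightedConnectome(labels=("A", "B", "C", "D"), weights=w)
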