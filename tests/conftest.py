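import numpy as np
import pytest

from mhvg import MultiplexVisibilityGraph, VisibilityGraph


def toy_graph(n_nodes, edges):
    return VisibilityGraph(n_nodes=n_nodes, edges=np.asarray(edges, dtype=np.int64))


def toy_multiplex(n_nodes, *edge_lists):
    return MultiplexVisibilityGraph(
        layers=tuple(toy_graph(n_nodes, e) for e in edge_lists), labels=None
    )


def hvg_oracle(x):
    """O(N^2) direct evaluation of the horizontal visibility criterion:
    (i, j) linked iff max of the intermediate values is strictly below
    both endpoints."""
    x = np.asarray(x, dtype=float)
    edges = set()
    for i in range(x.size - 1):
        running_max = -np.inf
        for j in range(i + 1, x.size):
            if running_max < x[i] and running_max < x[j]:
                edges.add((i, j))
            running_max = max(running_max, x[j])
    return edges


def nvg_oracle(x):
    """O(N^3) direct evaluation of the natural (chord) visibility
    criterion."""
    x = np.asarray(x, dtype=float)
    edges = set()
    for i in range(x.size - 1):
        for j in range(i + 1, x.size):
            if all(
                x[k] < x[i] + (x[j] - x[i]) * (k - i) / (j - i)
                for k in range(i + 1, j)
            ):
                edges.add((i, j))
    return edges


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
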