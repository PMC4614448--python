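"""Horizontal (and natural) visibility graphs of a single series.

The horizontal visibility graph (HVG) of an ordered series
``x(0), ..., x(N-1)`` places one node per time point and links ``i`` and
``j`` (``i < j``) iff every intermediate datum is strictly below the
smaller endpoint::

    x(k) < min(x(i), x(j))   for all  i < k < j.

Consecutive points are always linked (there is no intermediate datum),
so the graph is connected; it is outerplanar on the time line (no two
edges cross), and it is a subgraph of the natural visibility graph,
whose criterion is convexity (intermediate points strictly below the
chord).  Construction is a single stack pass, expected O(N) on noisy
data.

Ties follow the strict inequality: an intermediate value exactly equal
to the smaller endpoint blocks visibility.  This is a convention — it is
measure-zero for chaotic maps but matters for quantized data.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._kernels import hvg_edges
from .series import as_values

__all__ = [
    "VisibilityGraph",
    "build_hvg",
    "build_nvg",
    "degree_sequence",
    "degree_distribution",
]


@dataclass(frozen=True)
class VisibilityGraph:
    """Undirected graph on ``n_nodes`` 0-based time points.

    ``edges`` is an ``(E, 2)`` integer array with ``i < j`` per row,
    sorted lexicographically; this is the canonical representation used
    by the multiplex metrics and the on-disk edge-list format.
    """

    n_nodes: int
    edges: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        lo = np.minimum(edges[:, 0], edges[:, 1])
        hi = np.maximum(edges[:, 0], edges[:, 1])
        if edges.size and (lo.min() < 0 or hi.max() >= self.n_nodes):
            raise ValueError("edge endpoint outside [0, n_nodes)")
        if np.any(lo == hi):
            raise ValueError("self-loops are not allowed")
        edges = np.column_stack([lo, hi])
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        object.__setattr__(self, "edges", edges[order])

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.edges}

    def degree_sequence(self) -> np.ndarray:
        """Degree ``k_i`` of every node, in node order."""
        return np.bincount(self.edges.ravel(), minlength=self.n_nodes)

    def degree_distribution(self) -> dict[int, float]:
        """Empirical ``P(k)``: fraction of nodes with each degree."""
        ks, counts = np.unique(self.degree_sequence(), return_counts=True)
        return {int(k): float(c) / self.n_nodes for k, c in zip(ks, counts)}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        return g

    def adjacency_matrix(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int8)
        a[self.edges[:, 0], self.edges[:, 1]] = 1
        a[self.edges[:, 1], self.edges[:, 0]] = 1
        return a


def build_hvg(series) -> VisibilityGraph:
    """Horizontal visibility graph of an ordered series.

    Parameters
    ----------
    series : TimeSeries or 1-D array-like
        At least two finite values; NaN/inf raise ``ValueError`` naming
        the offending index.
    """
    x = as_values(series)
    return VisibilityGraph(n_nodes=x.size, edges=hvg_edges(x))


def build_nvg(series) -> VisibilityGraph:
    """Natural visibility graph: ``(i, j)`` linked iff every intermediate
    point lies strictly below the chord from ``(i, x_i)`` to ``(j, x_j)``.

    The HVG of the same series is always a subgraph.  O(N^2) pairwise
    construction; intended for small series and cross-checks.
    """
    x = as_values(series)
    n = x.size
    rows = []
    for i in range(n - 1):
        rows.append((i, i + 1))
        # max over k in (i, j) of the slope (x_k - x_i)/(k - i) must stay
        # strictly below the chord slope for j to be visible from i
        best = -np.inf
        for j in range(i + 2, n):
            slope_prev = (x[j - 1] - x[i]) / (j - 1 - i)
            if slope_prev > best:
                best = slope_prev
            if best < (x[j] - x[i]) / (j - i):
                rows.append((i, j))
    return VisibilityGraph(n_nodes=n, edges=np.array(rows, dtype=np.int64))


def degree_sequence(graph: VisibilityGraph) -> np.ndarray:
    return graph.degree_sequence()


def degree_distribution(graph: VisibilityGraph) -> dict[int, float]:
    return graph.degree_distribution()
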