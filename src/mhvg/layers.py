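"""Graph of layers: the functional-network projection of a multiplex.

The M layers become the nodes of a single weighted complete graph whose
edge weights are the interlayer degree mutual informations ``I_ab``.
Two sparse summaries are provided:

* **backbone** — add edges in decreasing weight order until the graph
  becomes a single connected component.  Ties are resolved with
  threshold semantics: every edge whose weight equals the connectivity
  threshold ``w_c`` is included, so the result is independent of the
  order in which equal-weight edges are listed.
* **maximum spanning tree** — the M-1 edge spanning tree of maximal
  total weight; it is always a subset of the backbone (the smallest MST
  edge weight equals ``w_c``).

Topological descriptors (edge count K, unweighted mean shortest-path
length L, mean local clustering C, total weight W) summarise either
subgraph; the hub fraction of an MST flags star-like concentration.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .multiplex import MultiplexVisibilityGraph, interlayer_mi_matrix

__all__ = [
    "graph_of_layers",
    "backbone",
    "maximum_spanning_tree",
    "summary_metrics",
    "hub_fraction",
]


def graph_of_layers(mux_or_weights, base=None, labels=None) -> nx.Graph:
    """Weighted complete graph on the M layers.

    Accepts a :class:`MultiplexVisibilityGraph` (weights are ``I_ab``,
    log base ``base``) or a symmetric nonnegative ``(M, M)`` weight
    matrix.  Nodes are layer indices ``0..M-1`` with a ``label``
    attribute; edges carry ``weight``.
    """
    if isinstance(mux_or_weights, MultiplexVisibilityGraph):
        if mux_or_weights.n_layers < 2:
            raise ValueError("graph of layers needs M >= 2 layers")
        w = interlayer_mi_matrix(mux_or_weights, base=base)
        labels = mux_or_weights.labels
    else:
        w = np.asarray(mux_or_weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] < 2:
            raise ValueError("weight matrix must be square with M >= 2")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
    m = w.shape[0]
    g = nx.Graph()
    for a in range(m):
        g.add_node(a, label=(labels[a] if labels is not None else str(a)))
    for a in range(m):
        for b in range(a + 1, m):
            g.add_edge(a, b, weight=float(w[a, b]))
    return g


def backbone(g: nx.Graph) -> nx.Graph:
    """Decreasing-weight edge addition until a single connected
    component forms; equal-weight edges at the final threshold are all
    included."""
    if g.number_of_nodes() < 2:
        raise ValueError("backbone needs at least 2 nodes")
    edges = sorted(
        g.edges(data="weight"), key=lambda e: (-e[2], e[0], e[1])
    )
    if any(not np.isfinite(w) for *_, w in edges):
        raise ValueError("backbone requires finite edge weights")
    parent = list(range(g.number_of_nodes()))
    node_ix = {v: i for i, v in enumerate(g.nodes())}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    sub = nx.Graph()
    sub.add_nodes_from(g.nodes(data=True))
    n_comp = g.number_of_nodes()
    i = 0
    while i < len(edges):
        # process one tie block of equal weight at a time
        j = i
        w = edges[i][2]
        while j < len(edges) and edges[j][2] == w:
            u, v, _ = edges[j]
            sub.add_edge(u, v, weight=w)
            ru, rv = find(node_ix[u]), find(node_ix[v])
            if ru != rv:
                parent[ru] = rv
                n_comp -= 1
            j += 1
        if n_comp == 1:
            return sub
        i = j
    raise ValueError("graph is disconnected even with all edges included")


def maximum_spanning_tree(g: nx.Graph) -> nx.Graph:
    """Spanning tree of maximal total weight (Kruskal; lexicographic
    tie-break for reproducibility)."""
    if not nx.is_connected(g):
        raise ValueError("maximum spanning tree requires a connected graph")
    tree = nx.Graph()
    tree.add_nodes_from(g.nodes(data=True))
    edges = sorted(g.edges(data="weight"), key=lambda e: (-e[2], e[0], e[1]))
    parent = {v: v for v in g.nodes()}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for u, v, w in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            tree.add_edge(u, v, weight=w)
    return tree


def summary_metrics(sub: nx.Graph) -> dict:
    """``{"K", "L", "C", "W"}`` of a connected subgraph: edge count,
    unweighted mean shortest-path length over node pairs, mean local
    clustering coefficient, and total edge weight."""
    if not nx.is_connected(sub):
        raise ValueError("mean shortest-path length is undefined on a disconnected graph")
    return {
        "K": sub.number_of_edges(),
        "L": float(nx.average_shortest_path_length(sub)),
        "C": float(nx.average_clustering(sub)),
        "W": float(sum(w for *_, w in sub.edges(data="weight", default=1.0))),
    }


def hub_fraction(tree: nx.Graph) -> float:
    """Largest node degree divided by M-1: 1.0 for a star, 1/(M-1) for
    a path."""
    m = tree.number_of_nodes()
    if m < 2:
        raise ValueError("hub fraction needs at least 2 nodes")
    return max(d for _, d in tree.degree()) / (m - 1)
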