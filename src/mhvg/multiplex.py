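"""Multiplex visibility graph and its two headline scalars.

Channel ``alpha`` of an M-dimensional signal becomes layer ``alpha``:
the HVG of that channel, over the shared set of N time-point nodes.
Cross-channel structure is quantified by

* the **average edge overlap** — over the union edge set, the mean
  fraction of layers an edge appears in::

      omega = sum_{i<j} sum_a a_ij^[a] /
              (M * sum_{i<j} [sum_a a_ij^[a] > 0])

  bounded in ``[1/M, 1]``; 1 iff all layers are identical, ``1/M`` iff
  every union edge lives in exactly one layer.  Computed by touching
  each stored edge once, i.e. O(N x M) for sparse HVG layers.

* the **interlayer degree mutual information** between the degree
  sequences of two layers, from the node-wise joint degree counts::

      I_ab = sum P(k_a, k_b) log[ P(k_a, k_b) / (P(k_a) P(k_b)) ]

  a plug-in (maximum-likelihood) estimate with no bias correction;
  natural log by default, configurable base.  The mean over distinct
  layer pairs is the scalar coherence index ``I``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hvg import VisibilityGraph, build_hvg
from .series import MultivariateSeries

__all__ = [
    "MultiplexVisibilityGraph",
    "JointDegreeDistribution",
    "build_multiplex",
    "average_edge_overlap",
    "joint_degree_distribution",
    "interlayer_mutual_information",
    "mean_interlayer_mutual_information",
    "interlayer_mi_matrix",
]


@dataclass(frozen=True)
class MultiplexVisibilityGraph:
    """Ordered layers (one :class:`VisibilityGraph` per channel) over a
    common node set."""

    layers: tuple
    labels: tuple

    def __post_init__(self):
        layers = tuple(self.layers)
        if not layers:
            raise ValueError("a multiplex needs at least one layer")
        n = layers[0].n_nodes
        if any(g.n_nodes != n for g in layers):
            raise ValueError("all layers must share the same node count")
        labels = self.labels
        if labels is None:
            labels = [f"s{a}" for a in range(len(layers))]
        labels = tuple(str(l) for l in labels)
        if len(labels) != len(layers):
            raise ValueError("one label per layer required")
        object.__setattr__(self, "layers", layers)
        object.__setattr__(self, "labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.layers[0].n_nodes

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def degree_matrix(self) -> np.ndarray:
        """``(M, N)`` array of node degrees per layer."""
        return np.stack([g.degree_sequence() for g in self.layers])


def build_multiplex(series, labels=None) -> MultiplexVisibilityGraph:
    """Build the M-layer multiplex visibility graph of a multichannel
    signal (rows = time, columns = channels); layer order follows
    channel order."""
    if isinstance(series, MultivariateSeries):
        mv = series
    else:
        mv = MultivariateSeries(np.asarray(series, dtype=float), labels=labels)
    layers = tuple(build_hvg(mv.values[:, a]) for a in range(mv.n_channels))
    return MultiplexVisibilityGraph(layers=layers, labels=tuple(mv.labels))


def _edge_keys(graph: VisibilityGraph) -> np.ndarray:
    return graph.edges[:, 0] * np.int64(graph.n_nodes) + graph.edges[:, 1]


def average_edge_overlap(mux: MultiplexVisibilityGraph) -> float:
    """Average edge overlap ``omega`` in ``[1/M, 1]``.

    Raises ``ValueError`` if the union edge set is empty (undefined
    metric) — impossible for HVG layers with N >= 2.
    """
    keys = [_edge_keys(g) for g in mux.layers]
    total = sum(k.size for k in keys)
    if total == 0:
        raise ValueError("average edge overlap is undefined on an empty multiplex")
    union_size = np.unique(np.concatenate(keys)).size
    return total / (mux.n_layers * union_size)


@dataclass(frozen=True)
class JointDegreeDistribution:
    """Node-wise joint degree counts ``N_{k_a, k_b}`` of two layers."""

    counts: dict
    n_nodes: int

    def probabilities(self) -> dict:
        """Joint ``P(k_a, k_b) = N_{k_a,k_b} / N``."""
        return {kk: c / self.n_nodes for kk, c in self.counts.items()}

    def marginal(self, axis: int) -> dict:
        """Integer degree counts of one layer (0 = first, 1 = second);
        summing the table over the other layer's degree recovers them
        exactly."""
        out: dict[int, int] = {}
        for kk, c in self.counts.items():
            out[kk[axis]] = out.get(kk[axis], 0) + c
        return out


def _check_layer(mux, a):
    if not (0 <= a < mux.n_layers):
        raise IndexError(f"layer index {a} out of range for M={mux.n_layers}")


def joint_degree_distribution(mux, alpha: int, beta: int) -> JointDegreeDistribution:
    """Tabulate ``(k_i^[alpha], k_i^[beta])`` over the N shared nodes."""
    _check_layer(mux, alpha)
    _check_layer(mux, beta)
    ka = mux.layers[alpha].degree_sequence()
    kb = mux.layers[beta].degree_sequence()
    pairs, counts = np.unique(np.column_stack([ka, kb]), axis=0, return_counts=True)
    table = {(int(p[0]), int(p[1])): int(c) for p, c in zip(pairs, counts)}
    return JointDegreeDistribution(counts=table, n_nodes=mux.n_nodes)


def _count_entropy(counts: np.ndarray, n: int) -> float:
    """Plug-in Shannon entropy (nats) of raw counts; 0 log 0 := 0."""
    p = counts[counts > 0] / n
    return float(-np.sum(p * np.log(p)))


def _mi_from_pairs(ka: np.ndarray, kb: np.ndarray, base=None) -> float:
    """Plug-in MI of two aligned nonnegative-integer sequences, as
    H(a) + H(b) - H(a, b) of the empirical counts."""
    ka = np.asarray(ka, dtype=np.int64)
    kb = np.asarray(kb, dtype=np.int64)
    n = ka.size
    width = int(kb.max()) + 1
    joint = np.bincount(ka * width + kb)
    mi = (
        _count_entropy(np.bincount(ka), n)
        + _count_entropy(np.bincount(kb), n)
        - _count_entropy(joint, n)
    )
    mi = max(mi, 0.0)  # clip tiny negative rounding residue
    if base is not None:
        mi /= np.log(base)
    return mi


def _pairwise_mi(deg: np.ndarray, pairs, base=None) -> list[float]:
    """MI for many layer pairs of one degree matrix, reusing the
    per-layer marginal entropies."""
    m, n = deg.shape
    width = int(deg.max()) + 1
    marginal = [_count_entropy(np.bincount(deg[a]), n) for a in range(m)]
    scale = np.log(base) if base is not None else 1.0
    out = []
    for a, b in pairs:
        joint = np.bincount(deg[a] * width + deg[b], minlength=width)
        mi = marginal[a] + marginal[b] - _count_entropy(joint, n)
        out.append(max(mi, 0.0) / scale)
    return out


def interlayer_mutual_information(mux, alpha: int, beta: int, base=None) -> float:
    """Mutual information between the degree sequences of two layers.

    Symmetric and nonnegative; ``alpha == beta`` returns the Shannon
    entropy of that layer's degree distribution.  ``base=None`` means
    natural log (nats); pass ``base=2`` for bits.
    """
    _check_layer(mux, alpha)
    _check_layer(mux, beta)
    deg = mux.degree_matrix()
    return _mi_from_pairs(deg[alpha], deg[beta], base=base)


def mean_interlayer_mutual_information(mux, base=None) -> float:
    """Mean of ``I_ab`` over the M(M-1)/2 unordered layer pairs."""
    m = mux.n_layers
    if m < 2:
        raise ValueError("mean interlayer mutual information needs M >= 2 layers")
    deg = mux.degree_matrix()
    pairs = [(a, b) for a in range(m) for b in range(a + 1, m)]
    return float(np.mean(_pairwise_mi(deg, pairs, base=base)))


def interlayer_mi_matrix(mux, base=None) -> np.ndarray:
    """Symmetric ``(M, M)`` matrix of ``I_ab`` with zero diagonal."""
    m = mux.n_layers
    deg = mux.degree_matrix()
    pairs = [(a, b) for a in range(m) for b in range(a + 1, m)]
    out = np.zeros((m, m))
    for (a, b), mi in zip(pairs, _pairwise_mi(deg, pairs, base=base)):
        out[a, b] = out[b, a] = mi
    return out
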