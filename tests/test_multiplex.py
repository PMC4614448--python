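"""Multiplex assembly, edge overlap and interlayer mutual information."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhvg import (
    average_edge_overlap,
    build_hvg,
    build_multiplex,
    interlayer_mutual_information,
    joint_degree_distribution,
    mean_interlayer_mutual_information,
)
from mhvg.multiplex import MultiplexVisibilityGraph, _mi_from_pairs
from .conftest import hvg_oracle, toy_graph, toy_multiplex


def overlap_oracle(mux):
    """Single-pass dictionary tally over every stored edge: the mean
    layer-multiplicity of the union edge set."""
    from collections import Counter

    tally = Counter()
    visits = 0
    for layer in mux.layers:
        for i, j in layer.edges:
            tally[(int(i), int(j))] += 1
            visits += 1
    assert visits == sum(g.n_edges for g in mux.layers)  # each edge touched once
    return sum(tally.values()) / (mux.n_layers * len(tally))


def random_toy_multiplex(rng, n_layers=None, n_nodes=None):
    m = n_layers or int(rng.integers(2, 6))
    n = n_nodes or int(rng.integers(8, 40))
    return build_multiplex(rng.normal(size=(n, m)))


def test_build_multiplex_layers_are_per_channel_hvgs(rng):
    x = rng.uniform(size=(200, 3))
    mux = build_multiplex(x)
    assert mux.n_layers == 3 and mux.n_nodes == 200
    for a in range(3):
        assert mux.layers[a].edge_set() == hvg_oracle(x[:, a])


def test_build_multiplex_single_channel_and_labels():
    mux = build_multiplex(np.array([[3.0], [1.0], [2.0]]), labels=["ch"])
    assert mux.n_layers == 1
    assert mux.layers[0].edge_set() == build_hvg([3, 1, 2]).edge_set()
    assert mux.labels == ("ch",)


def test_build_multiplex_rejects_mismatched_layers():
    with pytest.raises(ValueError):
        MultiplexVisibilityGraph(
            layers=(toy_graph(3, [(0, 1)]), toy_graph(4, [(0, 1)])), labels=None
        )


@pytest.mark.parametrize("m", [2, 3, 5])
def test_overlap_is_one_for_identical_layers(m):
    base = build_hvg(np.sin(np.arange(50) * 0.7))
    mux = MultiplexVisibilityGraph(layers=(base,) * m, labels=None)
    assert average_edge_overlap(mux) == 1.0


@pytest.mark.parametrize("m", [2, 3, 5])
def test_overlap_is_one_over_m_for_disjoint_layers(m):
    # layer a holds only edge (a, a+1): every union edge in exactly one layer
    mux = toy_multiplex(m + 1, *[[(a, a + 1)] for a in range(m)])
    assert average_edge_overlap(mux) == pytest.approx(1.0 / m)


def test_overlap_hand_count():
    mux = toy_multiplex(3, [(0, 1), (1, 2)], [(0, 1)])
    assert average_edge_overlap(mux) == pytest.approx(3 / 4)


def test_overlap_matches_tally_oracle_and_bounds(rng):
    for _ in range(30):
        mux = random_toy_multiplex(rng)
        omega = average_edge_overlap(mux)
        assert omega == pytest.approx(overlap_oracle(mux))
        assert 1 / mux.n_layers - 1e-12 <= omega <= 1 + 1e-12


def test_overlap_invariant_under_shared_relabeling(rng):
    mux = random_toy_multiplex(rng, n_layers=3, n_nodes=20)
    perm = rng.permutation(20)
    relabeled = MultiplexVisibilityGraph(
        layers=tuple(
            toy_graph(20, perm[g.edges]) for g in mux.layers
        ),
        labels=None,
    )
    assert average_edge_overlap(relabeled) == pytest.approx(average_edge_overlap(mux))


def test_joint_degree_distribution_examples():
    # two path-graph layers on 4 nodes
    path = [(0, 1), (1, 2), (2, 3)]
    mux = toy_multiplex(4, path, path)
    jd = joint_degree_distribution(mux, 0, 1)
    assert jd.counts == {(1, 1): 2, (2, 2): 2}
    # degrees [2,2,2] against [1,2,1]
    mux2 = toy_multiplex(3, [(0, 1), (1, 2), (0, 2)], [(0, 1), (1, 2)])
    assert joint_degree_distribution(mux2, 0, 1).counts == {(2, 1): 2, (2, 2): 1}
    # alpha == beta concentrates on the diagonal
    jd_diag = joint_degree_distribution(mux2, 1, 1)
    assert all(ka == kb for ka, kb in jd_diag.counts)


def test_joint_degree_marginalization_identity(rng):
    for _ in range(20):
        mux = random_toy_multiplex(rng)
        a, b = rng.choice(mux.n_layers, size=2, replace=False)
        jd = joint_degree_distribution(mux, int(a), int(b))
        assert sum(jd.counts.values()) == mux.n_nodes
        for axis, layer in ((0, int(a)), (1, int(b))):
            ks, cs = np.unique(
                mux.layers[layer].degree_sequence(), return_counts=True
            )
            assert jd.marginal(axis) == {int(k): int(c) for k, c in zip(ks, cs)}


def test_mi_self_is_degree_entropy(rng):
    mux = random_toy_multiplex(rng, n_layers=2, n_nodes=60)
    p = np.array(list(mux.layers[0].degree_distribution().values()))
    assert interlayer_mutual_information(mux, 0, 0) == pytest.approx(
        -(p * np.log(p)).sum()
    )


def test_mi_zero_under_independence():
    # joint counts exactly the product of uniform marginals
    ka = np.array([1, 1, 2, 2])
    kb = np.array([1, 2, 1, 2])
    assert _mi_from_pairs(ka, kb) == pytest.approx(0.0, abs=1e-12)


def test_mi_log2_for_perfectly_coupled_binary_degrees():
    n = 40
    ka = np.repeat([1, 2], n // 2)
    assert _mi_from_pairs(ka, ka, base=2) == pytest.approx(1.0)
    assert _mi_from_pairs(ka, ka) == pytest.approx(np.log(2))


def test_mi_symmetry_nonnegativity_and_entropy_bound(rng):
    for _ in range(20):
        mux = random_toy_multiplex(rng)
        a, b = rng.choice(mux.n_layers, size=2, replace=False)
        a, b = int(a), int(b)
        iab = interlayer_mutual_information(mux, a, b)
        assert iab == pytest.approx(interlayer_mutual_information(mux, b, a))
        assert iab >= 0.0
        ha = interlayer_mutual_information(mux, a, a)
        hb = interlayer_mutual_information(mux, b, b)
        assert iab <= min(ha, hb) + 1e-12


def test_mi_matches_sklearn_plugin_estimate(rng):
    """Independent plug-in MI oracle on the same degree pairs."""
    from sklearn.metrics import mutual_info_score

    mux = build_multiplex(rng.normal(size=(300, 4)))
    deg = mux.degree_matrix()
    for a in range(4):
        for b in range(a + 1, 4):
            assert interlayer_mutual_information(mux, a, b) == pytest.approx(
                mutual_info_score(deg[a], deg[b])
            )


def test_mean_mi_examples(rng):
    mux2 = random_toy_multiplex(rng, n_layers=2)
    assert mean_interlayer_mutual_information(mux2) == pytest.approx(
        interlayer_mutual_information(mux2, 0, 1)
    )
    base = build_hvg(np.sin(np.arange(40) * 1.3))
    same = MultiplexVisibilityGraph(layers=(base,) * 3, labels=None)
    p = np.array(list(base.degree_distribution().values()))
    assert mean_interlayer_mutual_information(same) == pytest.approx(
        -(p * np.log(p)).sum()
    )


def test_layer_index_and_m_errors(rng):
    mux = random_toy_multiplex(rng, n_layers=2)
    with pytest.raises(IndexError):
        interlayer_mutual_information(mux, 0, 5)
    single = MultiplexVisibilityGraph(layers=(mux.layers[0],), labels=None)
    with pytest.raises(ValueError):
        mean_interlayer_mutual_information(single)
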