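"""Metapath composition, neighbor-graph merging, features and file I/O."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ttgcn import (HeteroNetwork, Metapath, compose_metapath, default_metapaths,
                   initial_features, merge_neighbor_graphs, read_network,
                   write_network)
from ttgcn.hetnet import export_metapath_graph, read_metapath_graph


def brute_force_metapath(matrices, zero_diag=True, self_loops=True):
    """Path enumeration oracle: (i,j) connected iff some chain of nonzero
    entries links i to j through the listed matrices."""
    n = matrices[0].shape[0]
    m_last = matrices[-1].shape[1]
    adj = np.zeros((n, m_last))
    for i in range(n):
        frontier = {i}
        for M in matrices:
            nxt = set()
            for u in frontier:
                nxt.update(np.nonzero(M[u])[0])
            frontier = nxt
        for j in frontier:
            adj[i, j] = 1
    if zero_diag:
        np.fill_diagonal(adj, 0)
    if self_loops:
        adj = adj + np.eye(n)
    return adj


def test_drug_disease_drug_shared_disease_edge():
    # drugs r3 and r4 (indices 2,3) share disease d1 -> edge present
    ddis = np.array([[1, 0], [0, 0], [0, 1], [0, 1]], dtype=float)
    net = HeteroNetwork(4, 1, 2, 1, relations={"drug-disease": ddis})
    g = compose_metapath(net, Metapath("r-d-r", "drug", ("drug-disease", "~drug-disease")))
    assert g.adjacency[2, 3] == 1 and g.adjacency[3, 2] == 1
    assert g.adjacency[0, 1] == 0


def test_empty_relation_gives_identity_only():
    net = HeteroNetwork(5, 1, 1, 1, relations={"drug-drug": np.zeros((5, 5))})
    g = compose_metapath(net, Metapath("r-r", "drug", ("drug-drug",)))
    assert np.array_equal(g.adjacency, np.eye(5))


def test_rdr_matches_brute_force_enumeration():
    ddis = np.array([[1, 0], [1, 1], [0, 1], [0, 0]], dtype=float)
    net = HeteroNetwork(4, 1, 2, 1, relations={"drug-disease": ddis})
    g = compose_metapath(net, Metapath("r-d-r", "drug", ("drug-disease", "~drug-disease")))
    expect = brute_force_metapath([ddis, ddis.T])
    assert np.array_equal(g.adjacency, expect)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_compose_agrees_with_enumeration_on_random_networks(seed):
    rng = np.random.default_rng(seed)
    nd, ndis = rng.integers(2, 8), rng.integers(1, 6)
    ddis = (rng.random((nd, ndis)) < 0.4).astype(float)
    net = HeteroNetwork(int(nd), 1, int(ndis), 1, relations={"drug-disease": ddis})
    mp = Metapath("r-d-r", "drug", ("drug-disease", "~drug-disease"))
    g = compose_metapath(net, mp)
    assert np.array_equal(g.adjacency, brute_force_metapath([ddis, ddis.T]))


def test_palindromic_chain_is_symmetric(tiny_net):
    for mp in default_metapaths("drug") + default_metapaths("target"):
        g = compose_metapath(tiny_net, mp)
        assert np.array_equal(g.adjacency, g.adjacency.T), mp.name


def test_dimension_mismatch_names_offender():
    bad = Metapath("bad", "drug", ("drug-disease", "~drug-sideeffect"))
    with pytest.raises(ValueError, match="drug-sideeffect"):
        bad.validate()


def test_merge_union_and_idempotence(tiny_net):
    graphs = [compose_metapath(tiny_net, mp) for mp in default_metapaths("drug")]
    merged = merge_neighbor_graphs(graphs)
    union = np.zeros_like(merged.adjacency)
    for g in graphs:
        union = np.maximum(union, g.adjacency)
    assert np.array_equal(merged.adjacency, union)
    again = merge_neighbor_graphs([merged, merged])
    assert np.array_equal(again.adjacency, merged.adjacency)


def test_merge_rejects_mixed_anchor_types(tiny_net):
    gd = compose_metapath(tiny_net, default_metapaths("drug")[0])
    gt = compose_metapath(tiny_net, default_metapaths("target")[0])
    with pytest.raises(ValueError, match="anchor"):
        merge_neighbor_graphs([gd, gt])


def test_merge_is_monotone(tiny_net):
    graphs = [compose_metapath(tiny_net, mp) for mp in default_metapaths("drug")]
    before = merge_neighbor_graphs(graphs).adjacency
    richer = HeteroNetwork(4, 3, 2, 2, relations=dict(tiny_net.relations),
                           similarities=dict(tiny_net.similarities))
    dd = richer.relations["drug-drug"].copy()
    dd[2, 3] = dd[3, 2] = 1
    richer.relations["drug-drug"] = dd
    after = merge_neighbor_graphs(
        [compose_metapath(richer, mp) for mp in default_metapaths("drug")]).adjacency
    assert np.all(after >= before)


def test_initial_features_identity_fallback():
    dt = np.array([[1, 0, 1, 0, 0], [0, 1, 0, 0, 1]], dtype=float)
    net = HeteroNetwork(2, 5, 1, 1, relations={"drug-target": dt})
    F = initial_features(net, "drug")
    assert F.shape == (2, 7)
    assert np.array_equal(F[:, :2], np.eye(2))
    assert np.array_equal(F[:, 2:], dt)


def test_initial_features_row_sums(tiny_net):
    for t in ("drug", "target"):
        F = initial_features(tiny_net, t)
        sim = tiny_net.similarities[f"{t}-sim"]
        dt = tiny_net.relations["drug-target"]
        inter = dt if t == "drug" else dt.T
        assert np.allclose(F.sum(axis=1), sim.sum(axis=1) + inter.sum(axis=1))


def test_network_validation_catches_defects(tiny_net):
    bad = HeteroNetwork(4, 3, 2, 2, relations={"drug-drug": np.ones((4, 4))})
    with pytest.raises(ValueError, match="diagonal"):
        bad.validate()
    bad2 = HeteroNetwork(4, 3, 2, 2,
                         relations={"drug-target": np.full((4, 3), 0.5)})
    with pytest.raises(ValueError, match="binary"):
        bad2.validate()
    bad3 = HeteroNetwork(4, 3, 2, 2, relations={"drug-target": np.zeros((3, 3))})
    with pytest.raises(ValueError, match="shape"):
        bad3.validate()


def test_network_roundtrip_tsv(tiny_net, tmp_path):
    write_network(tiny_net, str(tmp_path))
    back = read_network(str(tmp_path))
    for name, mat in tiny_net.relations.items():
        assert np.array_equal(back.relations[name], mat), name
    for name, mat in tiny_net.similarities.items():
        assert np.allclose(back.similarities[name], mat), name


def test_metapath_graph_mtx_roundtrip(tiny_net, tmp_path):
    mp = default_metapaths("drug")[1]
    g = compose_metapath(tiny_net, mp)
    export_metapath_graph(g, tiny_net, str(tmp_path))
    back = read_metapath_graph(str(tmp_path / "r-d-r.mtx"), mp)
    assert np.array_equal(back.adjacency, g.adjacency)
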