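"""Feature computation against hand calculations and brute-force oracles.

The oracles are deliberately naive: neighbour-set arithmetic, explicit
per-node loops over a partition, and networkx's independent
implementations of the centrality measures.
"""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from commexplain import (
    RunEnsemble,
    assemble_feature_table,
    community_node_features,
    fixture_barbell,
    label_easy_hard,
    node_feature_table,
    pair_features,
    run_ensemble,
    strategic_undersample,
    structural_node_features,
)
from commexplain.coassoc import PairClassLabels
from commexplain.features import NODE_FEATURES, PAIR_FEATURES


def _manual_ensemble(G, partitions):
    return RunEnsemble(G, "manual", np.asarray(partitions), 0)


# --------------------------------------------------------------- fixtures
def test_barbell_structural_hand_values(barbell5):
    G, _ = barbell5
    f = structural_node_features(G)
    assert f.loc[1, "clustering_coefficient"] == pytest.approx(1.0)  # K4 neighbours
    assert f.loc[0, "clustering_coefficient"] == pytest.approx(2 * 6 / (5 * 4))
    # all 25 cross-clique pairs route through each portal
    assert f.loc[0, "betweenness"] > f.loc[1:4, "betweenness"].max()
    assert f.loc[0, "closeness"] == pytest.approx(9 / 13)


def test_path_graph_closeness():
    f = structural_node_features(nx.path_graph(3))
    assert f.loc[1, "closeness"] == pytest.approx(1.0)  # (3-1)/2


def test_barbell_community_hand_values(barbell5):
    G, _ = barbell5
    two_clique = [[0] * 5 + [1] * 5]
    f = community_node_features(G, _manual_ensemble(G, two_clique))
    # non-portal node: no external edges
    assert f.loc[1, ["e_out", "odf", "conductance"]].tolist() == [0, 0, 0]
    assert f.loc[1, "e_in"] == 4
    # portal node: one bridge edge out, w = 4 community-mates, |V| = 10
    assert f.loc[0, "conductance"] == pytest.approx(1 / 9)
    assert f.loc[0, "odf"] == pytest.approx(1 / 5)
    assert f.loc[0, "expansion"] == pytest.approx(1 / 4)
    assert f.loc[0, "cut_ratio"] == pytest.approx(1 / 6)


def test_community_features_average_over_runs(barbell5):
    G, _ = barbell5
    runs = [[0] * 5 + [1] * 5, [0] * 10]  # portal e_out: 1 then 0
    f = community_node_features(G, _manual_ensemble(G, runs))
    assert f.loc[0, "e_out"] == pytest.approx(0.5)


def test_barbell_pair_hand_values(barbell5):
    G, _ = barbell5
    f = pair_features(G, np.array([[1, 2], [0, 5], [1, 6]]))
    assert f.loc[(1, 2), "common_neighbours"] == 3  # nodes 0, 3, 4
    assert f.loc[(1, 2), "cosine_similarity"] == pytest.approx(3 / 4)
    assert f.loc[(1, 2), "jaccard"] == pytest.approx(3 / 5)
    assert f.loc[(0, 5), "common_neighbours"] == 0
    assert f.loc[(0, 5), "cosine_similarity"] == 0
    assert f.loc[(1, 6), "shortest_path_length"] == 3
    # every cross-clique geodesic uses the bridge, the most central edge
    eb = nx.edge_betweenness_centrality(G, normalized=False)
    assert f.loc[(1, 6), "max_edge_centrality"] == pytest.approx(max(eb.values()))


def test_identical_neighbourhood_jaccard_one():
    G = nx.complete_bipartite_graph(2, 3)
    f = pair_features(G, np.array([[0, 1]]))
    assert f.loc[(0, 1), "jaccard"] == pytest.approx(1.0)


# ------------------------------------------------- oracle equivalence
def test_structural_features_match_networkx_oracle(planted60):
    G, _ = planted60
    n = G.number_of_nodes()
    f = structural_node_features(G)
    assert np.allclose(f["degree"], [G.degree(v) for v in range(n)])
    nx_cc = nx.clustering(G)
    assert np.allclose(f["clustering_coefficient"], [nx_cc[v] for v in range(n)])
    nx_bet = nx.betweenness_centrality(G, normalized=False)
    assert np.allclose(f["betweenness"], [nx_bet[v] for v in range(n)], atol=1e-8)
    nx_clo = nx.closeness_centrality(G)
    assert np.allclose(f["closeness"], [nx_clo[v] for v in range(n)])
    sp = dict(nx.all_pairs_shortest_path_length(G))
    avg = [sum(sp[v].values()) / (n - 1) for v in range(n)]
    assert np.allclose(f["avg_shortest_path"], avg)
    # eigenvector centrality: dense eigendecomposition oracle + residual
    A = nx.to_numpy_array(G, nodelist=range(n))
    vals, vecs = np.linalg.eigh(A)
    lead = np.abs(vecs[:, -1])
    assert np.allclose(f["eigenvector_centrality"], lead, atol=1e-8)
    x = f["eigenvector_centrality"].to_numpy()
    assert np.linalg.norm(A @ x - vals[-1] * x) <= 1e-8


def _naive_community_features(G, labels):
    n = G.number_of_nodes()
    rows = {}
    for i in range(n):
        deg = G.degree(i)
        e_in = sum(1 for j in G.neighbors(i) if labels[j] == labels[i])
        e_out = deg - e_in
        w = sum(1 for j in range(n) if j != i and labels[j] == labels[i])
        c = 0
        for j in range(n):
            if j == i or labels[j] != labels[i]:
                continue
            shared = any(
                labels[k] == labels[i]
                for k in set(G.neighbors(i)) & set(G.neighbors(j))
            )
            c += shared
        rows[i] = {
            "e_in": e_in,
            "e_out": e_out,
            "e_in_over_e_out": e_in / max(e_out, 1),
            "odf": e_out / deg,
            "expansion": e_out / max(w, 1),
            "cut_ratio": e_out / (n - w),
            "conductance": e_out / (deg + e_in),
            "triangle_participation": c / max(w, 1),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def test_community_features_match_naive_oracle(planted60):
    G, truth = planted60
    rng = np.random.default_rng(3)
    runs = [
        np.array([truth[v] for v in range(60)]),
        rng.integers(0, 4, size=60),  # arbitrary noisy partition
        rng.integers(0, 2, size=60),
    ]
    f = community_node_features(G, _manual_ensemble(G, runs))
    oracle = sum(_naive_community_features(G, labels) for labels in runs) / 3
    for col in oracle.columns:
        assert np.allclose(f[col], oracle[col]), col


def test_pair_features_match_naive_oracle(planted60):
    G, _ = planted60
    rng = np.random.default_rng(1)
    nodes = np.arange(60)
    pairs = np.array([rng.choice(nodes, 2, replace=False) for _ in range(40)])
    f = pair_features(G, pairs)
    eb = nx.edge_betweenness_centrality(G, normalized=False)
    eb = {tuple(sorted(e)): v for e, v in eb.items()}
    for u, v in pairs:
        u, v = int(u), int(v)
        nu, nv = set(G.neighbors(u)), set(G.neighbors(v))
        d = nx.shortest_path_length(G, u, v)
        assert f.loc[(u, v), "shortest_path_length"] == d
        assert f.loc[(u, v), "common_neighbours"] == len(nu & nv)
        assert f.loc[(u, v), "cosine_similarity"] == pytest.approx(
            len(nu & nv) / np.sqrt(len(nu) * len(nv))
        )
        assert f.loc[(u, v), "jaccard"] == pytest.approx(len(nu & nv) / len(nu | nv))
        geo_edges = set()
        for path in nx.all_shortest_paths(G, u, v):
            geo_edges.update(
                tuple(sorted((path[i], path[i + 1]))) for i in range(len(path) - 1)
            )
        assert f.loc[(u, v), "max_edge_centrality"] == pytest.approx(
            max(eb[e] for e in geo_edges)
        )


def test_pair_features_rejects_identical_nodes(barbell5):
    with pytest.raises(ValueError):
        pair_features(barbell5[0], np.array([[2, 2]]))


def test_cosine_jaccard_order_agree_on_regular_graph():
    """With equal degrees both similarities are monotone in the common
    neighbour count, so they rank pairs identically."""
    G = nx.random_regular_graph(6, 30, seed=2)
    G = nx.relabel_nodes(G, {v: i for i, v in enumerate(sorted(G))})
    rng = np.random.default_rng(0)
    pairs = np.array([rng.choice(30, 2, replace=False) for _ in range(30)])
    f = pair_features(G, pairs)
    order_cos = np.argsort(f["cosine_similarity"].to_numpy(), kind="stable")
    order_jac = np.argsort(f["jaccard"].to_numpy(), kind="stable")
    assert np.array_equal(order_cos, order_jac)


# -------------------------------------------------- invariants & ranges
def test_feature_ranges_on_lfr(lfr_mu02):
    G, _ = lfr_mu02[0]
    ens = run_ensemble(G, "louvain", R=5, base_seed=0)
    f = node_feature_table(G, ens)
    unit = [
        "odf", "cut_ratio", "conductance", "triangle_participation",
        "clustering_coefficient",
    ]
    assert (f[unit] >= 0).all().all() and (f[unit] <= 1).all().all()
    assert (f["closeness"] > 0).all() and (f["closeness"] <= 1).all()
    assert (f["eigenvector_centrality"] >= 0).all()
    assert list(f.columns) == list(NODE_FEATURES)
    assert not f.isna().any().any()


def test_structural_features_independent_of_ensemble(barbell5):
    G, _ = barbell5
    e1 = run_ensemble(G, "louvain", 5, 0)
    e2 = run_ensemble(G, "lpa", 5, 99)
    t1 = node_feature_table(G, e1)
    t2 = node_feature_table(G, e2)
    structural = [
        "degree", "avg_shortest_path", "clustering_coefficient",
        "betweenness", "eigenvector_centrality", "closeness",
    ]
    assert t1[structural].equals(t2[structural])


# ------------------------------------------------------ table assembly
def test_assemble_node_table_shape(barbell5):
    G, _ = barbell5
    ens = run_ensemble(G, "louvain", 10, 0)
    ent = np.array([0.0, 0.01, 0.02, 0.03, 0.2, 0.21, 0.22, 0.0, 0.01, 0.3])
    labels = strategic_undersample(label_easy_hard(ent), ent)
    table = assemble_feature_table(node_feature_table(G, ens), labels)
    assert table.shape == (len(labels.selected), len(NODE_FEATURES) + 1)
    assert set(table["label"]) == {0, 1}


def test_assemble_pair_table_shape(barbell5):
    G, _ = barbell5
    i, j = np.triu_indices(10, k=1)
    same = np.array([(a < 5) == (b < 5) for a, b in zip(i, j)])
    sel = np.arange(0, len(i), 3)
    labels = PairClassLabels(i, j, same, sel)
    feats = pair_features(G, labels.selected_pairs())
    table = assemble_feature_table(feats, labels)
    assert table.shape == (len(sel), len(PAIR_FEATURES) + 1)
    assert list(table.columns[:-1]) == list(PAIR_FEATURES)


def test_assemble_missing_feature_errors(barbell5):
    G, _ = barbell5
    ens = run_ensemble(G, "louvain", 5, 0)
    feats = node_feature_table(G, ens).drop(index=3)
    ent = np.linspace(0, 0.4, 10)
    labels = label_easy_hard(ent)
    with pytest.raises(KeyError):
        assemble_feature_table(feats, labels)
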