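"""Interpretable node and node-pair features.

Fourteen node-level features and five pair-level features, all standard
social-network-analysis quantities. Six node features depend only on
graph structure (degree, average shortest path, clustering coefficient,
betweenness, eigenvector and closeness centrality). The other eight depend
on a community assignment; since the algorithms are stochastic, those are
evaluated against every run of an ensemble and averaged with equal weight
per run.

Community-dependent quantities for node ``i`` with respect to one run
(``w`` = number of *other* nodes sharing i's community; ``N`` = |V|):

====================  =====================================================
``e_in`` / ``e_out``  edges from i inside / outside its community
                      (``e_in + e_out = deg(i)``, asserted per run)
``e_in_over_e_out``   ``e_in / max(e_out, 1)`` (denominator floored so the
                      ratio stays finite when no edge leaves)
``odf``               out-degree fraction ``e_out / deg(i)``
``expansion``         ``e_out / w``
``cut_ratio``         ``e_out / (N - w)``
``conductance``       ``e_out / (deg(i) + e_in)``
``triangle_participation``
                      ``c_i / w`` where ``c_i`` counts community-mates j
                      with which i shares a common neighbour that itself
                      lies inside the community
====================  =====================================================

Betweenness (node and edge) is Brandes' unnormalized sum over unordered
pairs, endpoints excluded. Eigenvector centrality is the principal
eigenvector of the adjacency matrix, unit Euclidean norm, nonnegative.
Heavy structural quantities are delegated to igraph's C routines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spl
import networkx as nx

from .coassoc import NodeClassLabels, PairClassLabels
from .detectors import RunEnsemble, to_igraph

__all__ = [
    "NODE_FEATURES",
    "PAIR_FEATURES",
    "structural_node_features",
    "community_node_features",
    "node_feature_table",
    "pair_features",
    "assemble_feature_table",
]

#: Canonical column order of the node feature table.
NODE_FEATURES = (
    "degree",
    "e_in",
    "e_out",
    "e_in_over_e_out",
    "odf",
    "expansion",
    "cut_ratio",
    "conductance",
    "avg_shortest_path",
    "triangle_participation",
    "clustering_coefficient",
    "betweenness",
    "eigenvector_centrality",
    "closeness",
)

#: Canonical column order of the pair feature table.
PAIR_FEATURES = (
    "shortest_path_length",
    "common_neighbours",
    "max_edge_centrality",
    "cosine_similarity",
    "jaccard",
)


def _adjacency(G: nx.Graph) -> tuple[np.ndarray, sp.csr_matrix]:
    n = G.number_of_nodes()
    E = np.array(sorted(tuple(sorted(e)) for e in G.edges()), dtype=np.int64)
    A = sp.csr_matrix(
        (np.ones(len(E)), (E[:, 0], E[:, 1])), shape=(n, n)
    )
    A = A + A.T
    return E, A


def _eigenvector_centrality(A: sp.csr_matrix) -> np.ndarray:
    """Principal eigenvector, unit Euclidean norm, nonnegative orientation."""
    n = A.shape[0]
    v0 = np.full(n, 1 / np.sqrt(n))  # deterministic start vector
    vals, vecs = spl.eigsh(A.astype(np.float64), k=1, which="LA", v0=v0)
    x = vecs[:, 0]
    x = x / np.linalg.norm(x)
    if x.sum() < 0:
        x = -x
    # Perron-Frobenius: the principal eigenvector of a connected graph is
    # strictly positive; clip roundoff noise.
    return np.clip(x, 0.0, None)


def structural_node_features(G: nx.Graph) -> pd.DataFrame:
    """Community-independent node features, one row per node.

    Columns: degree, avg_shortest_path, clustering_coefficient,
    betweenness, eigenvector_centrality, closeness. Requires a connected
    graph of at least 3 nodes.
    """
    n = G.number_of_nodes()
    if n < 3:
        raise ValueError("need at least 3 nodes")
    if not nx.is_connected(G):
        raise ValueError("graph must be connected (shortest-path features)")
    g = to_igraph(G)
    D = np.asarray(g.distances(), dtype=np.float64)
    degree = np.asarray(g.degree(), dtype=np.float64)
    dist_sums = D.sum(axis=1)  # diagonal is 0
    out = pd.DataFrame(
        {
            "degree": degree,
            "avg_shortest_path": dist_sums / (n - 1),
            # degree <= 1 has no neighbour pair; coefficient defined as 0
            "clustering_coefficient": np.asarray(
                g.transitivity_local_undirected(mode="zero"), dtype=np.float64
            ),
            "betweenness": np.asarray(g.betweenness(), dtype=np.float64),
            "eigenvector_centrality": _eigenvector_centrality(_adjacency(G)[1]),
            "closeness": (n - 1) / dist_sums,
        }
    )
    out.index.name = "node"
    return out


def _per_run_community_features(
    E: np.ndarray,
    A_pattern: sp.csr_matrix,
    degree: np.ndarray,
    labels: np.ndarray,
    require_internal_neighbour: bool = True,
) -> dict[str, np.ndarray]:
    """Community-dependent features of every node for one partition."""
    n = len(degree)
    internal = labels[E[:, 0]] == labels[E[:, 1]]
    e_in = np.bincount(E[internal].ravel(), minlength=n).astype(np.float64)
    e_out = np.bincount(E[~internal].ravel(), minlength=n).astype(np.float64)
    assert np.array_equal(e_in + e_out, degree), "e_in + e_out must equal degree"
    sizes = np.bincount(labels)
    w = (sizes[labels] - 1).astype(np.float64)  # community-mates, i excluded
    w_safe = np.maximum(w, 1.0)  # singleton community: w = 0, c_i = 0 too

    rows = E[internal]
    Aint = sp.csr_matrix(
        (np.ones(len(rows)), (rows[:, 0], rows[:, 1])), shape=(n, n)
    )
    Aint = Aint + Aint.T
    if require_internal_neighbour:
        # j within two internal hops: middle node and j are community-mates
        B = (Aint @ Aint).tocsr()
    else:
        # common neighbour anywhere; j still restricted to i's community
        B = (A_pattern @ A_pattern).tocsr()
    B.setdiag(0)
    B.eliminate_zeros()
    if require_internal_neighbour:
        c = np.diff(B.indptr).astype(np.float64)
    else:
        Bc = B.tocoo()
        mate = labels[Bc.row] == labels[Bc.col]
        c = np.bincount(Bc.row[mate], minlength=n).astype(np.float64)

    return {
        "e_in": e_in,
        "e_out": e_out,
        "e_in_over_e_out": e_in / np.maximum(e_out, 1.0),
        "odf": e_out / degree,
        "expansion": e_out / w_safe,
        "cut_ratio": e_out / (n - w),
        "conductance": e_out / (degree + e_in),
        "triangle_participation": c / w_safe,
    }


def community_node_features(
    G: nx.Graph,
    ensemble: RunEnsemble,
    require_internal_neighbour: bool = True,
) -> pd.DataFrame:
    """Community-dependent node features averaged over the ensemble's runs.

    Each feature is evaluated against every run's partition and the
    arithmetic mean over runs is reported. ``require_internal_neighbour``
    selects the triangle-participation reading in which the shared
    neighbour must itself lie inside the community (default); the
    alternative counts any common neighbour while still requiring the
    counted node to be a community-mate.
    """
    E, A = _adjacency(G)
    degree = np.asarray(A.sum(axis=1)).ravel()
    acc: dict[str, np.ndarray] = {}
    for labels in ensemble.partitions:
        per_run = _per_run_community_features(
            E, A, degree, labels, require_internal_neighbour
        )
        for name, vals in per_run.items():
            acc[name] = acc.get(name, 0.0) + vals
    out = pd.DataFrame({name: vals / ensemble.R for name, vals in acc.items()})
    out.index.name = "node"
    return out


def node_feature_table(G: nx.Graph, ensemble: RunEnsemble) -> pd.DataFrame:
    """All 14 node features in canonical column order."""
    full = structural_node_features(G).join(community_node_features(G, ensemble))
    return full[list(NODE_FEATURES)]


def pair_features(
    G: nx.Graph,
    pairs: np.ndarray,
    geodesic_edges: str = "union",
) -> pd.DataFrame:
    """Five pair features for the given ``(k, 2)`` array of node pairs.

    ``max_edge_centrality`` is the maximum Brandes edge betweenness over
    the edges of shortest paths between the pair. With several geodesics
    the quantity is ambiguous; ``geodesic_edges="union"`` (default) takes
    the union of edges on *all* shortest paths (deterministic and
    path-choice-free), ``"single"`` follows one canonical shortest path.
    """
    pairs = np.asarray(pairs, dtype=np.int64)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be a (k, 2) array")
    if (pairs[:, 0] == pairs[:, 1]).any():
        raise ValueError("pairs must consist of two distinct nodes")
    if geodesic_edges not in ("union", "single"):
        raise ValueError("geodesic_edges must be 'union' or 'single'")
    g = to_igraph(G)
    E, A = _adjacency(G)
    degree = np.asarray(A.sum(axis=1)).ravel()
    eb_ig = np.asarray(g.edge_betweenness(), dtype=np.float64)  # igraph edge order
    eid = np.array(
        [g.get_eid(int(u), int(v)) for u, v in E], dtype=np.int64
    )
    edge_bet = eb_ig[eid]  # aligned to E's row order

    sources = np.unique(pairs)
    D_sub = np.asarray(g.distances(source=[int(s) for s in sources]))
    row_of = {int(s): r for r, s in enumerate(sources)}

    neigh = [set(G.neighbors(v)) for v in range(G.number_of_nodes())]
    records = []
    for u, v in pairs:
        u, v = int(u), int(v)
        du, dv = D_sub[row_of[u]], D_sub[row_of[v]]
        d = du[v]
        n_uv = len(neigh[u] & neigh[v])
        union = degree[u] + degree[v] - n_uv
        if geodesic_edges == "union":
            on_path = (du[E[:, 0]] + 1 + dv[E[:, 1]] == d) | (
                du[E[:, 1]] + 1 + dv[E[:, 0]] == d
            )
            mec = edge_bet[on_path].max()
        else:
            path = g.get_shortest_paths(u, to=v)[0]
            ids = [
                g.get_eid(path[i], path[i + 1]) for i in range(len(path) - 1)
            ]
            mec = eb_ig[ids].max()
        records.append(
            {
                "i": u,
                "j": v,
                "shortest_path_length": d,
                "common_neighbours": float(n_uv),
                "max_edge_centrality": float(mec),
                "cosine_similarity": n_uv / np.sqrt(degree[u] * degree[v]),
                "jaccard": n_uv / union,
            }
        )
    out = pd.DataFrame.from_records(records).set_index(["i", "j"])
    return out[list(PAIR_FEATURES)]


def assemble_feature_table(
    features: pd.DataFrame,
    labels: NodeClassLabels | PairClassLabels,
) -> pd.DataFrame:
    """Join features with binary labels, restricted to the training subset.

    For node labels the ``label`` column is 1 = hard to cluster; for pair
    labels 1 = same community. Raises if any selected key lacks features.
    """
    if isinstance(labels, NodeClassLabels):
        keys = labels.selected
        y = labels.hard[keys].astype(int)
        expected = list(NODE_FEATURES)
        index = pd.Index(keys, name="node")
    else:
        sel = labels.selected_pairs()
        y = labels.same[labels.selected].astype(int)
        expected = list(PAIR_FEATURES)
        index = pd.MultiIndex.from_arrays([sel[:, 0], sel[:, 1]], names=["i", "j"])
    missing = index.difference(features.index)
    if len(missing):
        raise KeyError(f"features missing for {len(missing)} selected keys")
    table = features.loc[index, expected].copy()
    if table.isna().any().any():
        raise ValueError("feature table contains missing values")
    table["label"] = np.asarray(y)
    return table
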