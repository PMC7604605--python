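"""Weighted nodal and global graph metrics.

All metrics treat the connectome as an undirected weighted graph. Shortest
paths map weights to lengths as 1/w, so stronger connections are shorter;
disconnected pairs have infinite length and contribute zero to efficiency.

Nodal: strength S_i, nodal efficiency E_nod_i, local clustering C_i
(Onnela geometric-mean form with weights normalised by the matrix maximum),
betweenness centrality B_i (ordered-pair normalisation, values in [0, 1]),
and vulnerability V_i (proportional drop in global efficiency upon node
deletion).

Global: global efficiency E_glob (mean nodal efficiency), local efficiency
E_loc (mean efficiency of neighbor-induced subgraphs), clustering
coefficient C_p (mean C_i), and characteristic path length L_p defined as
1/E_glob (harmonic-mean convention).
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from sklearn.base import BaseEstimator, TransformerMixin

from .atlas import Connectome

__all__ = [
    "edge_lengths",
    "shortest_path_lengths",
    "nodal_strength",
    "nodal_efficiency",
    "local_clustering",
    "betweenness",
    "vulnerability",
    "global_efficiency",
    "local_efficiency",
    "clustering_coefficient",
    "characteristic_path_length",
    "GraphMetrics",
    "NODAL_METRICS",
    "GLOBAL_METRICS",
]

NODAL_METRICS = ("strength", "nodal_efficiency", "clustering", "betweenness",
                 "vulnerability")
GLOBAL_METRICS = ("global_efficiency", "local_efficiency",
                  "clustering_coefficient", "characteristic_path_length")


def _weights(c) -> np.ndarray:
    return c.weights if isinstance(c, Connectome) else np.asarray(c, dtype=float)


def edge_lengths(c) -> np.ndarray:
    """Per-edge lengths 1/w_ij for w_ij > 0; +inf where there is no edge."""
    w = _weights(c)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, np.inf)
    np.fill_diagonal(lengths, np.inf)
    return lengths


def shortest_path_lengths(c) -> np.ndarray:
    """All-pairs shortest weighted path lengths L_ij (inf if disconnected)."""
    w = _weights(c)
    n = w.shape[0]
    lengths = edge_lengths(w)
    finite = np.isfinite(lengths)
    graph = csr_matrix((lengths[finite], np.nonzero(finite)), shape=(n, n))
    dist = dijkstra(graph, directed=False)
    np.fill_diagonal(dist, 0.0)
    return dist


def nodal_strength(c) -> np.ndarray:
    """S_i: sum of the weights of all connections of node i."""
    return _weights(c).sum(axis=1)


def _efficiency_from_dist(dist: np.ndarray) -> np.ndarray:
    n = dist.shape[0]
    if n < 2:
        return np.zeros(n)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & (dist > 0), 1.0 / dist, 0.0)
    return inv.sum(axis=1) / (n - 1)


def nodal_efficiency(c) -> np.ndarray:
    """E_nod_i = mean over j != i of 1/L_ij (zero for disconnected pairs)."""
    return _efficiency_from_dist(shortest_path_lengths(c))


def global_efficiency(c) -> float:
    """E_glob: average of the nodal efficiencies over all nodes."""
    w = _weights(c)
    if w.shape[0] == 0:
        return 0.0
    return float(nodal_efficiency(w).mean())


def local_clustering(c) -> np.ndarray:
    """C_i: weighted clustering, geometric mean of triangle weights.

    Weights are normalised by the matrix maximum before the cube root
    (Onnela convention), so C_i is in [0, 1]; nodes with fewer than two
    connections have C_i = 0.
    """
    w = _weights(c)
    n = w.shape[0]
    wmax = w.max(initial=0.0)
    if wmax == 0:
        return np.zeros(n)
    a = np.cbrt(w / wmax)
    k = np.count_nonzero(w, axis=1).astype(float)
    tri = np.einsum("ij,jh,hi->i", a, a, a)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ci = np.where(denom > 0, tri / denom, 0.0)
    return ci


def clustering_coefficient(c) -> float:
    """C_p: mean of the local clustering coefficients over all nodes."""
    return float(local_clustering(c).mean())


def betweenness(c) -> np.ndarray:
    """B_i: fraction of shortest paths containing i as an intermediate.

    Ordered-pair normalisation 1/((N-1)(N-2)); shortest paths are computed
    on edge lengths 1/w.
    """
    w = _weights(c)
    n = w.shape[0]
    if n < 3:
        return np.zeros(n)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(w, 1))
    g.add_weighted_edges_from(
        ((int(i), int(j), 1.0 / w[i, j]) for i, j in zip(ii, jj)), weight="length"
    )
    bc = nx.betweenness_centrality(g, normalized=True, weight="length")
    return np.array([bc[i] for i in range(n)])


def vulnerability(c) -> np.ndarray:
    """V_i: proportional drop in global efficiency when node i is removed.

    Raises
    ------
    ValueError
        If the network's global efficiency is zero (vulnerability undefined).
    """
    w = _weights(c)
    n = w.shape[0]
    eg = global_efficiency(w)
    if eg <= 0:
        raise ValueError("vulnerability undefined: global efficiency is zero")
    v = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        v[i] = (eg - global_efficiency(w[np.ix_(mask, mask)])) / eg
    return v


def local_efficiency(c) -> float:
    """E_loc: mean global efficiency of each node's neighbor subgraph.

    Nodes with fewer than two neighbors contribute zero.
    """
    w = _weights(c)
    n = w.shape[0]
    if n == 0:
        return 0.0
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size < 2:
            continue
        total += global_efficiency(w[np.ix_(nbrs, nbrs)])
    return total / n


def characteristic_path_length(c) -> float:
    """L_p = 1/E_glob; +inf when the network has no connected pairs."""
    eg = global_efficiency(c)
    return 1.0 / eg if eg > 0 else np.inf


class GraphMetrics(BaseEstimator, TransformerMixin):
    """Compute the full nodal + global metric suite per subject.

    ``transform`` accepts an iterable of :class:`Connectome` (or raw square
    weight matrices) and returns a tidy DataFrame with columns
    ``subject_id, node, metric, value``; global metrics use node ``GLOBAL``.

    Parameters
    ----------
    include_vulnerability : bool, default True
        Vulnerability requires one extra all-pairs shortest-path pass per
        node; disable for speed when V_i is not needed.
    """

    def __init__(self, include_vulnerability: bool = True):
        self.include_vulnerability = include_vulnerability

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> pd.DataFrame:
        rows = []
        for idx, c in enumerate(X):
            sid = c.subject_id if isinstance(c, Connectome) else f"S{idx:03d}"
            labels = c.labels if isinstance(c, Connectome) else [
                str(i) for i in range(np.asarray(c).shape[0])
            ]
            w = _weights(c)
            dist = shortest_path_lengths(w)
            e_nod = _efficiency_from_dist(dist)
            e_glob = float(e_nod.mean()) if e_nod.size else 0.0
            nodal = {
                "strength": nodal_strength(w),
                "nodal_efficiency": e_nod,
                "clustering": local_clustering(w),
                "betweenness": betweenness(w),
            }
            if self.include_vulnerability:
                nodal["vulnerability"] = vulnerability(w)
            for metric, values in nodal.items():
                for lab, val in zip(labels, values):
                    rows.append((sid, lab, metric, float(val)))
            glob = {
                "global_efficiency": e_glob,
                "local_efficiency": local_efficiency(w),
                "clustering_coefficient": clustering_coefficient(w),
                "characteristic_path_length": 1.0 / e_glob if e_glob > 0 else np.inf,
            }
            for metric, val in glob.items():
                rows.append((sid, "GLOBAL", metric, float(val)))
        return pd.DataFrame(rows, columns=["subject_id", "node", "metric", "value"])
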