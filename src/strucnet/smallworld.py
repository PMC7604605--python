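"""Small-worldness against degree-matched random networks.

gamma = C_p / mean(C_p of nulls), lambda = L_p / mean(L_p of nulls),
sigma = gamma / lambda; sigma > 1 indicates small-world organisation.

Null networks share the original's node count, edge count, and degree
sequence. Topology is randomised by Maslov-Sneppen double-edge swaps
(10 x edge-count attempted swaps by default, rejecting self-loops and
multi-edges); the original weight multiset is then permuted uniformly at
random onto the rewired edges, preserving the weight distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .atlas import Connectome
from .metrics import _weights, clustering_coefficient, global_efficiency

__all__ = ["SmallWorldResult", "matched_random_network", "small_worldness",
           "SmallWorldness"]


@dataclass
class SmallWorldResult:
    """Normalised clustering/path-length ratios for one network."""

    gamma: float
    lam: float
    sigma: float
    cp: float
    lp: float
    cp_rand: float
    lp_rand: float
    n_random: int


def _rewire_edges(edges: np.ndarray, n_nodes: int, rng: np.random.Generator,
                  n_swap_per_edge: int) -> np.ndarray:
    """Degree-preserving double-edge swaps on an undirected edge list.

    Attempts ``n_swap_per_edge * m`` swaps; proposals creating self-loops or
    duplicate edges are rejected and count against the budget. Rigid
    topologies (e.g. a triangle) that admit no valid swap are returned
    unchanged.
    """
    edges = edges.copy()
    m = len(edges)
    if m < 2:
        return edges
    edge_set = {frozenset(e) for e in map(tuple, edges)}
    attempts = n_swap_per_edge * m
    pick = rng.integers(0, m, size=(attempts, 2))
    orient = rng.integers(0, 2, size=attempts)
    for t in range(attempts):
        a, b = pick[t]
        if a == b:
            continue
        u, v = edges[a]
        x, y = edges[b]
        if orient[t]:
            x, y = y, x
        # proposed replacement: (u, x) and (v, y)
        if u == x or v == y:
            continue
        new1, new2 = frozenset((u, x)), frozenset((v, y))
        if new1 == new2 or new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(frozenset((u, v)))
        edge_set.discard(frozenset((x, y)))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[a] = (u, x)
        edges[b] = (v, y)
    return edges


def matched_random_network(c, rng=None, n_swap_per_edge: int = 10):
    """Degree-matched random surrogate of a weighted network.

    Preserves node count, edge count, and the exact degree sequence;
    reassigns the original weight multiset uniformly at random onto the
    rewired edges. Returns the same container type as the input
    (:class:`Connectome` or bare matrix).
    """
    rng = np.random.default_rng(rng)
    w = _weights(c)
    n = w.shape[0]
    ii, jj = np.nonzero(np.triu(w, 1))
    if len(ii) < 2:
        raise ValueError("rewiring requires at least 2 edges")
    edges = np.column_stack([ii, jj])
    new_edges = _rewire_edges(edges, n, rng, n_swap_per_edge)
    weights = w[ii, jj]
    perm = rng.permutation(len(weights))
    out = np.zeros_like(w)
    out[new_edges[:, 0], new_edges[:, 1]] = weights[perm]
    out = out + out.T
    if isinstance(c, Connectome):
        return Connectome(atlas=c.atlas, weights=out,
                          subject_id=f"{c.subject_id}:null")
    return out


def small_worldness(c, n_random: int = 100, rng=None,
                    n_swap_per_edge: int = 10) -> SmallWorldResult:
    """Compute sigma = gamma/lambda against ``n_random`` matched nulls.

    Raises
    ------
    ValueError
        If the network has zero global efficiency, or the null ensemble's
        mean clustering coefficient is zero (degenerate null).
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(rng)
    w = _weights(c)
    cp = clustering_coefficient(w)
    eg = global_efficiency(w)
    if eg <= 0:
        raise ValueError("small-worldness undefined: global efficiency is zero")
    lp = 1.0 / eg
    cps = np.empty(n_random)
    lps = np.empty(n_random)
    for r in range(n_random):
        null = matched_random_network(w, rng=rng, n_swap_per_edge=n_swap_per_edge)
        cps[r] = clustering_coefficient(null)
        eg_null = global_efficiency(null)
        lps[r] = 1.0 / eg_null if eg_null > 0 else np.inf
    cp_rand = float(cps.mean())
    lp_rand = float(lps.mean())
    if cp_rand == 0:
        raise ValueError("degenerate null: mean clustering of the ensemble is zero")
    gamma = cp / cp_rand
    lam = lp / lp_rand
    return SmallWorldResult(gamma=gamma, lam=lam, sigma=gamma / lam,
                            cp=cp, lp=lp, cp_rand=cp_rand, lp_rand=lp_rand,
                            n_random=n_random)


class SmallWorldness(BaseEstimator, TransformerMixin):
    """Per-subject small-worldness over a cohort of connectomes.

    ``transform`` returns a DataFrame with one row per subject:
    subject_id, cp, lp, cp_rand, lp_rand, gamma, lambda, sigma.

    Parameters
    ----------
    n_random : int, default 100
        Size of the matched-random-network ensemble per subject.
    n_swap_per_edge : int, default 10
        Attempted double-edge swaps per edge per null realisation.
    random_state : int or Generator, optional
        Seeds the entire ensemble; fixed seeds give bit-reproducible sigma.
    """

    def __init__(self, n_random: int = 100, n_swap_per_edge: int = 10,
                 random_state=None):
        self.n_random = n_random
        self.n_swap_per_edge = n_swap_per_edge
        self.random_state = random_state

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> pd.DataFrame:
        rng = np.random.default_rng(self.random_state)
        rows = []
        for idx, c in enumerate(X):
            sid = c.subject_id if isinstance(c, Connectome) else f"S{idx:03d}"
            res = small_worldness(c, n_random=self.n_random, rng=rng,
                                  n_swap_per_edge=self.n_swap_per_edge)
            rows.append((sid, res.cp, res.lp, res.cp_rand, res.lp_rand,
                         res.gamma, res.lam, res.sigma))
        return pd.DataFrame(rows, columns=["subject_id", "cp", "lp", "cp_rand",
                                           "lp_rand", "gamma", "lambda", "sigma"])
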