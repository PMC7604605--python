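"""Network-based statistic (NBS).

Each edge present in enough subjects gets a group-contrast GLM t statistic
(age and sex as covariates). Edges whose one-tailed parametric p falls
below an initial threshold are kept, their connected components extracted,
and each component's extent (edge count) is compared against the
permutation null distribution of the maximum component extent, giving
family-wise-corrected component p-values. Decreased and enhanced
connectivity are tested as separate one-tailed analyses sharing one
permutation stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._glm import freedman_lane_t, permutation_indices
from .atlas import CohortDesign, Connectome

__all__ = ["NBSComponent", "nbs_compare", "NBS"]

DIRECTIONS = ("decrease", "increase")


@dataclass
class NBSComponent:
    """A connected set of supra-threshold edges with its permutation p."""

    edges: list[tuple[int, int]]
    direction: str
    p_value: float
    edge_labels: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_nodes(self) -> int:
        return len({n for e in self.edges for n in e})

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "n_edges": self.n_edges,
            "n_nodes": self.n_nodes,
            "p_value": self.p_value,
            "edges": [list(e) for e in (self.edge_labels or self.edges)],
        }


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self):
        self.parent: dict[int, int] = {}

    def find(self, x: int) -> int:
        parent = self.parent
        root = parent.setdefault(x, x)
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def edge_components(pairs: np.ndarray) -> list[list[tuple[int, int]]]:
    """Group an edge list into connected components (lists of edges)."""
    uf = _UnionFind()
    for i, j in pairs:
        uf.union(int(i), int(j))
    comps: dict[int, list[tuple[int, int]]] = {}
    for i, j in pairs:
        comps.setdefault(uf.find(int(i)), []).append((int(i), int(j)))
    return sorted(comps.values(), key=len, reverse=True)


def _max_extent(pairs: np.ndarray) -> int:
    if len(pairs) == 0:
        return 0
    uf = _UnionFind()
    for i, j in pairs:
        uf.union(int(i), int(j))
    counts: dict[int, int] = {}
    for i, j in pairs:
        r = uf.find(int(i))
        counts[r] = counts.get(r, 0) + 1
    return max(counts.values())


def _stack_weights(connectomes) -> tuple[np.ndarray, list[str] | None]:
    mats, labels = [], None
    for c in connectomes:
        if isinstance(c, Connectome):
            mats.append(c.weights)
            labels = c.labels
        else:
            mats.append(np.asarray(c, dtype=float))
    return np.stack(mats), labels


def nbs_compare(
    connectomes,
    design: CohortDesign,
    initial_p: float = 0.005,
    n_perm: int = 10000,
    alpha: float | None = 0.05,
    seed=None,
    edge_fraction: float = 0.5,
) -> dict[str, list[NBSComponent]]:
    """Identify group-difference subnetworks by component extent.

    Parameters
    ----------
    connectomes : sequence of Connectome (or square weight matrices), one
        per subject, in design order.
    initial_p : one-tailed parametric p threshold for edge screening.
    alpha : component significance level; None returns every component with
        its permutation p.
    edge_fraction : an edge is tested if nonzero in at least this fraction
        of either group's subjects.

    Returns
    -------
    dict mapping "decrease"/"increase" (patients vs controls) to lists of
    :class:`NBSComponent`. No surviving edge yields an empty list.
    """
    if not (0 < initial_p <= 1):
        raise ValueError("initial_p must be in (0, 1]")
    stack, labels = _stack_weights(connectomes)
    n_subj, n = stack.shape[0], stack.shape[1]
    if n_subj != design.n_subjects:
        raise ValueError("number of connectomes does not match design")
    iu, ju = np.triu_indices(n, k=1)
    edge_vals = stack[:, iu, ju]                     # (n_subj, n_pairs)

    nz = edge_vals > 0
    ctrl = design.group == 0
    pat = design.group == 1
    frac_ctrl = nz[ctrl].mean(axis=0)
    frac_pat = nz[pat].mean(axis=0)
    tested = (frac_ctrl >= edge_fraction) | (frac_pat >= edge_fraction)
    # constant edges cannot be fit
    tested &= np.ptp(edge_vals, axis=0) > 0
    if not tested.any():
        return {d: [] for d in DIRECTIONS}

    y = edge_vals[:, tested]
    pairs = np.column_stack([iu[tested], ju[tested]])
    X, Z, cidx = design.design_matrices()
    rng = np.random.default_rng(seed)
    perms = permutation_indices(rng, n_subj, n_perm)
    t_obs, t_perm, dof = freedman_lane_t(y, X, Z, cidx, perms)
    t_crit = stats.t.isf(initial_p, dof)

    signed = {"increase": 1.0, "decrease": -1.0}
    out: dict[str, list[NBSComponent]] = {}
    null_max = {
        d: np.array([
            _max_extent(pairs[s * t_perm[b] > t_crit]) for b in range(n_perm)
        ])
        for d, s in signed.items()
    }
    for d, s in signed.items():
        mask = s * t_obs > t_crit
        comps = edge_components(pairs[mask])
        results = []
        for comp in comps:
            extent = len(comp)
            p = (1.0 + (null_max[d] >= extent).sum()) / (1.0 + n_perm)
            if alpha is None or p < alpha:
                edge_labels = (
                    [(labels[i], labels[j]) for i, j in comp] if labels else []
                )
                results.append(NBSComponent(edges=comp, direction=d,
                                            p_value=float(p),
                                            edge_labels=edge_labels))
        out[d] = results
    return out


class NBS:
    """Estimator form of :func:`nbs_compare`.

    ``fit(connectomes, design)`` stores ``components_`` (dict of direction
    -> list of :class:`NBSComponent`).
    """

    def __init__(self, initial_p: float = 0.005, n_perm: int = 10000,
                 alpha: float | None = 0.05, edge_fraction: float = 0.5,
                 random_state=None):
        self.initial_p = initial_p
        self.n_perm = n_perm
        self.alpha = alpha
        self.edge_fraction = edge_fraction
        self.random_state = random_state

    def get_params(self, deep=True):
        return {
            "initial_p": self.initial_p, "n_perm": self.n_perm,
            "alpha": self.alpha, "edge_fraction": self.edge_fraction,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y: CohortDesign):
        self.components_ = nbs_compare(
            X, y, initial_p=self.initial_p, n_perm=self.n_perm,
            alpha=self.alpha, seed=self.random_state,
            edge_fraction=self.edge_fraction,
        )
        return self
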