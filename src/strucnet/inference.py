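"""Permutation inference for the group-contrast GLM with FWE correction.

Scalar metrics are tested with a one-tailed permutation test of the group
coefficient in y ~ group + age + sex (Freedman-Lane residual permutation,
add-one p-value estimator). Nodal metrics share a single permutation stream
across nodes, and family-wise error is controlled by the permutation
distribution of the maximum statistic over nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._glm import freedman_lane_t, permutation_indices
from .atlas import CohortDesign

__all__ = ["PermutationTestResult", "permutation_glm", "nodal_comparison",
           "PermutationGLM", "NodalPermutationGLM"]

_TAILS = ("greater", "less")


@dataclass
class PermutationTestResult:
    """One metric's permutation test outcome for a given tail."""

    observed_stat: float
    p_uncorrected: float
    n_perm: int
    tail: str
    p_fwe: float | None = None


def _check_design(values: np.ndarray, design: CohortDesign) -> None:
    if values.shape[0] != design.n_subjects:
        raise ValueError(
            f"{values.shape[0]} responses for {design.n_subjects} subjects"
        )
    for g in (0, 1):
        if (design.group == g).sum() < 2:
            raise ValueError("need at least 2 subjects per group")
    if np.isnan(values).any():
        raise ValueError("missing values in response")


def _tail_p(t_obs: np.ndarray, t_perm: np.ndarray, tail: str) -> np.ndarray:
    """Add-one permutation p-values; never exactly zero."""
    B = t_perm.shape[0]
    if tail == "greater":
        exceed = (t_perm >= t_obs[None, :]).sum(axis=0)
    else:
        exceed = (t_perm <= t_obs[None, :]).sum(axis=0)
    return (1.0 + exceed) / (1.0 + B)


def permutation_glm(values, design: CohortDesign, n_perm: int = 10000,
                    tail: str | None = None, seed=None):
    """Permutation test of a per-subject scalar between groups.

    Parameters
    ----------
    values : (n_subjects,) array of the metric being compared.
    tail : {"greater", "less"} or None
        Direction of the patient-minus-control contrast. When None, both
        one-tailed tests are run on a shared permutation stream and a dict
        ``{"greater": ..., "less": ...}`` is returned.

    Raises
    ------
    ValueError
        If the response is constant (zero residual variance), a group has
        fewer than 2 subjects, or values are missing.
    """
    values = np.asarray(values, dtype=float).ravel()
    _check_design(values, design)
    X, Z, cidx = design.design_matrices()
    if np.ptp(values) == 0:
        raise ValueError("degenerate test: response is identical for all subjects")
    rng = np.random.default_rng(seed)
    perms = permutation_indices(rng, design.n_subjects, n_perm)
    t_obs, t_perm, _ = freedman_lane_t(values[:, None], X, Z, cidx, perms)
    if not np.isfinite(t_obs[0]):
        raise ValueError("degenerate test: zero residual variance")
    results = {}
    for t in _TAILS:
        p = _tail_p(t_obs, t_perm, t)[0]
        results[t] = PermutationTestResult(
            observed_stat=float(t_obs[0]), p_uncorrected=float(p),
            n_perm=n_perm, tail=t,
        )
    return results if tail is None else results[tail]


def nodal_comparison(metric_table, design: CohortDesign, n_perm: int = 10000,
                     tail: str | None = None, seed=None) -> pd.DataFrame:
    """Node-wise permutation GLM with max-statistic FWE correction.

    Parameters
    ----------
    metric_table : (n_subjects, n_nodes) array or DataFrame
        One metric's values, rows indexed by subject in design order.

    Returns
    -------
    DataFrame with columns node, tail, t_observed, p_uncorrected, p_fwe.
    For each node p_fwe is the proportion of permutations whose maximum
    statistic across all nodes meets or exceeds that node's observed
    statistic (minimum for the "less" tail).
    """
    if isinstance(metric_table, pd.DataFrame):
        node_labels = [str(c) for c in metric_table.columns]
        y = metric_table.to_numpy(dtype=float)
    else:
        y = np.asarray(metric_table, dtype=float)
        node_labels = [str(i) for i in range(y.shape[1])]
    _check_design(y, design)
    X, Z, cidx = design.design_matrices()
    if (np.ptp(y, axis=0) == 0).any():
        raise ValueError("degenerate test: a node's response is constant")
    rng = np.random.default_rng(seed)
    perms = permutation_indices(rng, design.n_subjects, n_perm)
    t_obs, t_perm, _ = freedman_lane_t(y, X, Z, cidx, perms)

    tails = _TAILS if tail is None else (tail,)
    rows = []
    for t in tails:
        p_unc = _tail_p(t_obs, t_perm, t)
        if t == "greater":
            extremes = t_perm.max(axis=1)              # (B,)
            fwe_exceed = (extremes[:, None] >= t_obs[None, :]).sum(axis=0)
        else:
            extremes = t_perm.min(axis=1)
            fwe_exceed = (extremes[:, None] <= t_obs[None, :]).sum(axis=0)
        p_fwe = (1.0 + fwe_exceed) / (1.0 + n_perm)
        for k, lab in enumerate(node_labels):
            rows.append((lab, t, float(t_obs[k]), float(p_unc[k]),
                         float(p_fwe[k])))
    return pd.DataFrame(rows, columns=["node", "tail", "t_observed",
                                       "p_uncorrected", "p_fwe"])


class PermutationGLM(BaseEstimator):
    """Estimator form of :func:`permutation_glm`.

    ``fit(values, design)`` stores ``results_`` (dict of tail ->
    :class:`PermutationTestResult`, or a single result when ``tail`` is set).
    """

    def __init__(self, n_perm: int = 10000, tail: str | None = None,
                 random_state=None):
        self.n_perm = n_perm
        self.tail = tail
        self.random_state = random_state

    def fit(self, X, y: CohortDesign):
        self.results_ = permutation_glm(X, y, n_perm=self.n_perm,
                                        tail=self.tail, seed=self.random_state)
        return self


class NodalPermutationGLM(BaseEstimator):
    """Estimator form of :func:`nodal_comparison`.

    ``fit(metric_table, design)`` stores the node-wise result table in
    ``results_``.
    """

    def __init__(self, n_perm: int = 10000, tail: str | None = None,
                 random_state=None):
        self.n_perm = n_perm
        self.tail = tail
        self.random_state = random_state

    def fit(self, X, y: CohortDesign):
        self.results_ = nodal_comparison(X, y, n_perm=self.n_perm,
                                         tail=self.tail, seed=self.random_state)
        return self
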