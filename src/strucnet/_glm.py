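"""Batched Freedman-Lane permutation machinery for the group-contrast GLM.

The model is y ~ intercept + group + age + sex. Nuisance signal is removed
by fitting the reduced (covariates-only) model; its residuals are permuted,
added back to the reduced fit, and the full-model t statistic for the group
contrast is recomputed for each permutation. All responses (nodes, edges)
share one permutation stream so max-statistic FWE is exact.
"""

from __future__ import annotations

import numpy as np

__all__ = ["permutation_indices", "glm_t", "freedman_lane_t"]


def permutation_indices(rng: np.random.Generator, n: int, n_perm: int) -> np.ndarray:
    """(n_perm, n) array of row permutations."""
    return np.array([rng.permutation(n) for _ in range(n_perm)])


def glm_t(y: np.ndarray, X: np.ndarray, cidx: int) -> tuple[np.ndarray, int]:
    """t statistic for coefficient ``cidx`` of OLS fits of each column of y.

    y : (n, m); returns (t (m,), residual dof).
    """
    n, p = X.shape
    dof = n - p
    if dof <= 0:
        raise ValueError("design has no residual degrees of freedom")
    pinv = np.linalg.pinv(X)
    xtx_inv = pinv @ pinv.T
    cc = xtx_inv[cidx, cidx]
    beta = pinv @ y
    resid = y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[cidx] / np.sqrt(sigma2 * cc)
    return t, dof


def freedman_lane_t(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    cidx: int,
    perms: np.ndarray,
    chunk: int = 64,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Observed and permuted group-contrast t statistics.

    Parameters
    ----------
    y : (n, m) response matrix (one column per node/edge/metric).
    X : (n, p) full design; Z : (n, p0) reduced design without the contrast.
    cidx : column of X holding the group regressor.
    perms : (B, n) permutation index array.
    chunk : permutations processed per batch (memory control).

    Returns
    -------
    t_obs : (m,), t_perm : (B, m), dof : int
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] != X.shape[0]:
        y = y.T
    n, p = X.shape
    dof = n - p
    pinv = np.linalg.pinv(X)
    xtx_inv = pinv @ pinv.T
    cc = xtx_inv[cidx, cidx]

    t_obs, _ = glm_t(y, X, cidx)

    pinv_z = np.linalg.pinv(Z)
    fitted_z = Z @ (pinv_z @ y)          # (n, m)
    resid_z = y - fitted_z

    B = perms.shape[0]
    m = y.shape[1]
    t_perm = np.empty((B, m))
    for start in range(0, B, chunk):
        idx = perms[start:start + chunk]              # (b, n)
        ystar = fitted_z[None, :, :] + resid_z[idx]   # (b, n, m)
        beta = np.einsum("pn,bnm->bpm", pinv, ystar)
        resid = ystar - np.einsum("np,bpm->bnm", X, beta)
        sigma2 = (resid**2).sum(axis=1) / dof         # (b, m)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm[start:start + idx.shape[0]] = beta[:, cidx, :] / np.sqrt(sigma2 * cc)
    return t_obs, t_perm, dof
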