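"""Group-level hub identification from betweenness centrality.

A node is a hub when its group-mean betweenness is at least one standard
deviation above the average across nodes (mean and SD taken over the 82
nodes of the group-mean profile). The hub table reports group-mean
betweenness and strength per hub, sorted by descending betweenness.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["identify_hubs"]


def identify_hubs(betweenness_table, strength_table=None,
                  node_labels=None) -> pd.DataFrame:
    """Identify hubs of one group from per-subject nodal betweenness.

    Parameters
    ----------
    betweenness_table : (n_subjects, n_nodes) array or DataFrame of B_i.
    strength_table : optional matching table of nodal strength S_i; when
        given, mean strength is reported alongside.
    node_labels : node names; defaults to the DataFrame columns or indices.

    Returns
    -------
    DataFrame with columns region, hemisphere, mean_betweenness,
    mean_strength, sorted by descending mean betweenness (region label as
    tie-break). A zero across-node SD is degenerate: no node can sit one SD
    above the mean, so an empty table is returned with a warning.
    """
    if isinstance(betweenness_table, pd.DataFrame):
        if node_labels is None:
            node_labels = [str(c) for c in betweenness_table.columns]
        b = betweenness_table.to_numpy(dtype=float)
    else:
        b = np.atleast_2d(np.asarray(betweenness_table, dtype=float))
        if node_labels is None:
            node_labels = [str(i) for i in range(b.shape[1])]
    if b.shape[0] < 1:
        raise ValueError("need at least one subject")
    mean_b = b.mean(axis=0)
    mu = mean_b.mean()
    sd = mean_b.std(ddof=1) if mean_b.size > 1 else 0.0
    if sd == 0:
        warnings.warn(
            "across-node SD of mean betweenness is zero; hub criterion "
            "degenerate, returning no hubs", UserWarning, stacklevel=2,
        )
        is_hub = np.zeros(mean_b.size, dtype=bool)
    else:
        is_hub = mean_b >= mu + sd

    if strength_table is not None:
        s = (strength_table.to_numpy(dtype=float)
             if isinstance(strength_table, pd.DataFrame)
             else np.atleast_2d(np.asarray(strength_table, dtype=float)))
        mean_s = s.mean(axis=0)
    else:
        mean_s = np.full(mean_b.size, np.nan)

    rows = []
    for k in np.flatnonzero(is_hub):
        label = node_labels[k]
        region, _, hemi = label.rpartition(".")
        if hemi not in ("L", "R"):
            region, hemi = label, ""
        rows.append((region or label, hemi, float(mean_b[k]), float(mean_s[k])))
    df = pd.DataFrame(rows, columns=["region", "hemisphere",
                                     "mean_betweenness", "mean_strength"])
    return df.sort_values(["mean_betweenness", "region"],
                          ascending=[False, True]).reset_index(drop=True)
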