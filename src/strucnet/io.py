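"""Readers and writers for the tabular interchange formats.

Connectomes travel as labeled square TSV matrices ("STG.L"-style headers);
streamline summaries as an edge table (node_a, node_b, count,
mean_length_mm) plus a node table (node, volume_mm3); cohorts as CSV with
subject_id, group, age, sex; metrics as tidy TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import Atlas, CohortDesign, Connectome, StreamlineSummary

__all__ = [
    "read_connectome_table", "write_connectome",
    "read_streamline_summary", "write_streamline_summary",
    "read_cohort", "write_cohort",
]


def write_connectome(c: Connectome, path) -> None:
    df = pd.DataFrame(c.weights, index=c.labels, columns=c.labels)
    # default float formatting is the shortest round-trip repr: lossless
    df.to_csv(path, sep="\t")


def read_connectome_table(path, atlas: Atlas, subject_id: str | None = None) -> Connectome:
    """Read a labeled square weight matrix, validating labels against the atlas.

    Raises
    ------
    ValueError
        For non-square files, unknown node labels, or labels out of atlas
        order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.shape[0] != df.shape[1]:
        raise ValueError(
            f"{path.name}: matrix is {df.shape[0]}x{df.shape[1]}, expected square"
        )
    labels = [str(c) for c in df.columns]
    if list(df.index.astype(str)) != labels:
        raise ValueError(f"{path.name}: row labels differ from column labels")
    expected = atlas.labels
    unknown = [l for l in labels if l not in set(expected)]
    if unknown:
        raise ValueError(f"{path.name}: unknown node label {unknown[0]!r}")
    if labels != expected:
        raise ValueError(f"{path.name}: node labels are not in atlas order")
    sid = subject_id if subject_id is not None else path.stem
    return Connectome(atlas=atlas, weights=df.to_numpy(dtype=float), subject_id=sid)


def write_streamline_summary(s: StreamlineSummary, edge_path, node_path,
                             atlas: Atlas) -> None:
    iu, ju = np.nonzero(np.triu(s.counts, 1))
    pd.DataFrame({
        "node_a": [atlas[i].label for i in iu],
        "node_b": [atlas[j].label for j in ju],
        "count": s.counts[iu, ju],
        "mean_length_mm": s.mean_lengths[iu, ju],
    }).to_csv(edge_path, sep="\t", index=False)
    pd.DataFrame({
        "node": atlas.labels,
        "volume_mm3": s.volumes,
    }).to_csv(node_path, sep="\t", index=False)


def read_streamline_summary(edge_path, node_path, atlas: Atlas,
                            subject_id: str = "") -> StreamlineSummary:
    edges = pd.read_csv(edge_path, sep="\t")
    nodes = pd.read_csv(node_path, sep="\t")
    n = len(atlas)
    counts = np.zeros((n, n), dtype=int)
    lengths = np.full((n, n), np.nan)
    for _, r in edges.iterrows():
        i = atlas.index_of(str(r["node_a"]))
        j = atlas.index_of(str(r["node_b"]))
        counts[i, j] = counts[j, i] = int(r["count"])
        lengths[i, j] = lengths[j, i] = float(r["mean_length_mm"])
    volumes = np.full(n, np.nan)
    for _, r in nodes.iterrows():
        volumes[atlas.index_of(str(r["node"]))] = float(r["volume_mm3"])
    return StreamlineSummary(counts=counts, mean_lengths=lengths,
                             volumes=volumes, subject_id=subject_id)


def write_cohort(design: CohortDesign, path) -> None:
    design.to_frame().to_csv(path, index=False)


def read_cohort(path) -> CohortDesign:
    return CohortDesign.from_frame(pd.read_csv(path))
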