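"""Weighted connectome construction from streamline summaries.

Connection strength between regions i and j is the streamline count
corrected for fiber length and ROI volume:

    w_ij = (2 / (V_i + V_j)) * n_ij / l_ij        (correction="length_volume")

with n_ij set to zero below a minimum streamline count (default 3) to
suppress spurious connections. Alternative correction modes keep the raw
count or apply only the length correction.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .atlas import Atlas, Connectome, StreamlineSummary

__all__ = ["build_connectome", "connectome_density", "ConnectomeBuilder"]

_CORRECTIONS = ("raw", "length", "length_volume")


def build_connectome(
    summary: StreamlineSummary,
    atlas: Atlas,
    min_streamlines: int = 3,
    correction: str = "length_volume",
) -> Connectome:
    """Build a subject's weighted connectivity matrix.

    Pairs with fewer than ``min_streamlines`` streamlines get weight zero.
    Retained pairs are weighted by streamline count divided by mean fiber
    length and (for ``correction="length_volume"``) by the mean of the two
    ROI volumes.

    Raises
    ------
    ValueError
        If a retained pair lacks a mean length, or a node lacks a positive
        volume while the volume correction is requested.
    """
    if correction not in _CORRECTIONS:
        raise ValueError(f"correction must be one of {_CORRECTIONS}, got {correction!r}")
    if min_streamlines < 0:
        raise ValueError("min_streamlines must be >= 0")
    n = summary.n_nodes
    if n != len(atlas):
        raise ValueError(
            f"summary has {n} nodes but atlas has {len(atlas)}"
        )
    counts = summary.counts.astype(float)
    keep = counts >= max(min_streamlines, 1)
    np.fill_diagonal(keep, False)

    kept_pairs = np.argwhere(np.triu(keep, 1))
    if correction in ("length", "length_volume"):
        lengths = summary.mean_lengths
        for i, j in kept_pairs:
            if not np.isfinite(lengths[i, j]) or lengths[i, j] <= 0:
                raise ValueError(
                    f"missing or nonpositive mean length for retained pair "
                    f"({atlas[i].label}, {atlas[j].label})"
                )
    if correction == "length_volume":
        for i, j in kept_pairs:
            for k in (i, j):
                if not np.isfinite(summary.volumes[k]) or summary.volumes[k] <= 0:
                    raise ValueError(
                        f"missing or nonpositive volume for node {atlas[k].label} "
                        f"required by retained pair ({atlas[i].label}, {atlas[j].label})"
                    )

    w = np.where(keep, counts, 0.0)
    if correction in ("length", "length_volume"):
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(keep, w / summary.mean_lengths, 0.0)
    if correction == "length_volume":
        vsum = summary.volumes[:, None] + summary.volumes[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(keep, 2.0 * w / vsum, 0.0)
    np.fill_diagonal(w, 0.0)
    return Connectome(atlas=atlas, weights=w, subject_id=summary.subject_id)


def connectome_density(c: Connectome) -> float:
    """Fraction of off-diagonal node pairs with a nonzero connection."""
    n = c.n_nodes
    if n < 2:
        return 0.0
    nonzero = np.count_nonzero(np.triu(c.weights, 1))
    return nonzero / (n * (n - 1) / 2)


class ConnectomeBuilder(BaseEstimator, TransformerMixin):
    """Transformer from streamline summaries to weighted connectomes.

    Parameters
    ----------
    atlas : Atlas
        Node set all summaries must conform to.
    min_streamlines : int, default 3
        Pairs with fewer streamlines are zeroed before correction.
    correction : {"length_volume", "length", "raw"}
        Weighting scheme, see :func:`build_connectome`.
    """

    def __init__(self, atlas=None, min_streamlines: int = 3,
                 correction: str = "length_volume"):
        self.atlas = atlas
        self.min_streamlines = min_streamlines
        self.correction = correction

    def fit(self, X, y=None):
        self.atlas_ = self.atlas if self.atlas is not None else _default_atlas()
        return self

    def transform(self, X) -> list[Connectome]:
        """X : iterable of StreamlineSummary -> list of Connectome."""
        if not hasattr(self, "atlas_"):
            self.fit(X)
        return [
            build_connectome(s, self.atlas_, self.min_streamlines, self.correction)
            for s in X
        ]


def _default_atlas() -> Atlas:
    from .atlas import load_default_atlas

    return load_default_atlas()
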