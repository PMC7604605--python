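"""Domain types for the 82-region parcellation, connectomes, and cohorts.

The default atlas is the Desikan-Killiany cortical parcellation (34 regions
per hemisphere) extended with 7 subcortical gray-matter structures per
hemisphere: 82 nodes, 41 per hemisphere, 68 cortical + 14 subcortical.
Node order is all left-hemisphere regions first, then right, with cortical
regions before subcortical within each hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtlasNode",
    "Atlas",
    "Connectome",
    "StreamlineSummary",
    "CohortDesign",
    "load_default_atlas",
    "validate_connectome",
]


@dataclass(frozen=True)
class AtlasNode:
    """One gray-matter region of interest.

    Parameters
    ----------
    index : int
        0-based position in the atlas ordering.
    name : str
        Full anatomical name, e.g. ``"Superior temporal gyrus"``.
    abbreviation : str
        Short code, e.g. ``"STG"``; unique within a hemisphere.
    hemisphere : {"L", "R"}
    tissue_class : {"cortical", "subcortical"}
    """

    index: int
    name: str
    abbreviation: str
    hemisphere: str
    tissue_class: str

    def __post_init__(self) -> None:
        if self.hemisphere not in ("L", "R"):
            raise ValueError(f"hemisphere must be 'L' or 'R', got {self.hemisphere!r}")
        if self.tissue_class not in ("cortical", "subcortical"):
            raise ValueError(f"unknown tissue_class {self.tissue_class!r}")

    @property
    def label(self) -> str:
        """Hemisphere-qualified label, e.g. ``"STG.L"``."""
        return f"{self.abbreviation}.{self.hemisphere}"


class Atlas:
    """An ordered collection of :class:`AtlasNode`.

    Abbreviations must be unique within each hemisphere; node ``index``
    fields must match list positions.
    """

    def __init__(self, nodes: Iterable[AtlasNode]):
        self.nodes: tuple[AtlasNode, ...] = tuple(nodes)
        for pos, node in enumerate(self.nodes):
            if node.index != pos:
                raise ValueError(
                    f"node {node.label} has index {node.index}, expected {pos}"
                )
        for hemi in ("L", "R"):
            abbrs = [n.abbreviation for n in self.nodes if n.hemisphere == hemi]
            if len(abbrs) != len(set(abbrs)):
                raise ValueError(f"duplicate abbreviations in hemisphere {hemi}")
        self._label_to_index = {n.label: n.index for n in self.nodes}

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)

    def __getitem__(self, i: int) -> AtlasNode:
        return self.nodes[i]

    @property
    def labels(self) -> list[str]:
        return [n.label for n in self.nodes]

    def index_of(self, label: str) -> int:
        try:
            return self._label_to_index[label]
        except KeyError:
            raise KeyError(f"unknown node label {label!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [n.index for n in self.nodes],
                "name": [n.name for n in self.nodes],
                "abbreviation": [n.abbreviation for n in self.nodes],
                "hemisphere": [n.hemisphere for n in self.nodes],
                "tissue_class": [n.tissue_class for n in self.nodes],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Atlas":
        nodes = [
            AtlasNode(
                index=int(r["index"]),
                name=str(r["name"]),
                abbreviation=str(r["abbreviation"]),
                hemisphere=str(r["hemisphere"]),
                tissue_class=str(r["tissue_class"]),
            )
            for _, r in df.iterrows()
        ]
        return cls(nodes)


def load_default_atlas() -> Atlas:
    """Load the bundled 82-node atlas (68 cortical + 14 subcortical regions).

    Returns an :class:`Atlas` ordered left hemisphere first then right,
    cortical before subcortical within each hemisphere.
    """
    with resources.files("strucnet").joinpath("data/dk82_atlas.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return Atlas.from_frame(df)


@dataclass
class Connectome:
    """One subject's symmetric nonnegative weighted connectivity matrix.

    ``weights[i, j]`` is the connection strength w_ij between atlas nodes i
    and j (dimensionless, >= 0, zero diagonal).
    """

    atlas: Atlas
    weights: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError(f"weights must be square, got shape {self.weights.shape}")
        if self.weights.shape[0] != len(self.atlas):
            raise ValueError(
                f"weights dimension {self.weights.shape[0]} does not match "
                f"atlas size {len(self.atlas)}"
            )

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def labels(self) -> list[str]:
        return self.atlas.labels


@dataclass
class StreamlineSummary:
    """Per-pair streamline counts and lengths plus per-node ROI volumes.

    Attributes
    ----------
    counts : (N, N) int array
        Symmetric streamline counts n_ij, zero diagonal.
    mean_lengths : (N, N) float array
        Mean fiber length l_ij in mm wherever ``counts > 0`` (NaN elsewhere).
    volumes : (N,) float array
        ROI volumes V_i in mm^3, strictly positive.
    """

    counts: np.ndarray
    mean_lengths: np.ndarray
    volumes: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.mean_lengths = np.asarray(self.mean_lengths, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        n = self.counts.shape[0]
        if self.counts.shape != (n, n) or self.mean_lengths.shape != (n, n):
            raise ValueError("counts and mean_lengths must be square and congruent")
        if self.volumes.shape != (n,):
            raise ValueError("volumes must have one entry per node")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("streamline counts must be symmetric")
        if (self.counts < 0).any():
            raise ValueError("streamline counts must be nonnegative")
        present = self.counts > 0
        if np.isnan(self.mean_lengths[present]).any():
            raise ValueError("mean length missing for a pair with streamlines")

    @property
    def n_nodes(self) -> int:
        return self.counts.shape[0]


@dataclass
class CohortDesign:
    """Subject-level design: binary group plus age and sex covariates.

    ``group`` is coded 0 = control, 1 = patient; ``sex`` 0/1. The group
    contrast of the general linear model ``y ~ group + age + sex`` is the
    quantity all permutation tests are about.
    """

    subject_ids: Sequence[str]
    group: np.ndarray
    age: np.ndarray
    sex: np.ndarray

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=float)
        n = len(self.subject_ids)
        for name, arr in (("group", self.group), ("age", self.age), ("sex", self.sex)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one value per subject")
            if np.isnan(arr).any():
                raise ValueError(f"missing values in covariate {name}")
        if not set(np.unique(self.group)) <= {0.0, 1.0}:
            raise ValueError("group must be coded 0 (control) / 1 (patient)")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def design_matrices(self) -> tuple[np.ndarray, np.ndarray, int]:
        """Full design X = [1, group, age, sex], reduced Z = [1, age, sex].

        Returns ``(X, Z, contrast_index)`` with ``contrast_index`` pointing
        at the group column of X.
        """
        n = self.n_subjects
        ones = np.ones(n)
        X = np.column_stack([ones, self.group, self.age, self.sex])
        Z = np.column_stack([ones, self.age, self.sex])
        return X, Z, 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": list(self.subject_ids),
                "group": self.group.astype(int),
                "age": self.age,
                "sex": self.sex.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortDesign":
        return cls(
            subject_ids=list(df["subject_id"].astype(str)),
            group=df["group"].to_numpy(),
            age=df["age"].to_numpy(),
            sex=df["sex"].to_numpy(),
        )


def validate_connectome(c: Connectome, atol: float = 0.0) -> list[str]:
    """Check symmetry, zero diagonal, nonnegativity, and dimension.

    Returns a list of human-readable violation descriptions; an empty list
    means the connectome is valid. Never raises.
    """
    violations: list[str] = []
    w = c.weights
    if w.shape[0] != len(c.atlas):
        violations.append(
            f"dimension {w.shape[0]} does not match atlas size {len(c.atlas)}"
        )
    asym = np.argwhere(np.abs(w - w.T) > atol)
    if asym.size:
        i, j = asym[0]
        violations.append(
            f"asymmetry: w[{i},{j}]={w[i, j]!r} != w[{j},{i}]={w[j, i]!r} "
            f"({len(asym) // 2 or len(asym)} pair(s))"
        )
    if np.abs(np.diag(w)).max(initial=0.0) > atol:
        violations.append("nonzero diagonal entries present")
    neg = np.argwhere(w < -atol)
    if neg.size:
        i, j = neg[0]
        violations.append(f"negative weight at [{i},{j}]: {w[i, j]!r}")
    if np.isnan(w).any():
        violations.append("NaN weights present")
    return violations
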