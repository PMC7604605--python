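"""Synthetic connectome cohorts with planted group differences.

Every subject in a simulated cohort shares one backbone topology — by
default a ring lattice with rewired shortcuts (Watts-Strogatz, k = 8
neighbors, rewiring probability 0.1), which gives the small-world
organisation real structural connectomes show. Backbone edge weights are
log-normal (heavy-tailed, strictly positive, scaled so that the implied
streamline counts per edge are in the tens, as in whole-brain
tractography); each subject multiplies them by independent log-normal
noise. Patient subjects additionally scale a designated connected edge set
by an attenuation/amplification factor, which is the planted group effect
the inference modules are asked to recover. Age and sex covariates follow
a typical young-adult case-control cohort (27 controls, 14 patients).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .atlas import Atlas, CohortDesign, Connectome, StreamlineSummary, load_default_atlas

__all__ = ["EffectSpec", "SimulationConfig", "GroundTruth", "simulate_cohort",
           "simulate_streamline_summary", "select_connected_edges"]


@dataclass
class EffectSpec:
    """A planted group effect: patient weights on ``edges`` are multiplied
    by ``factor`` (< 1 attenuation, > 1 amplification, 1 no effect)."""

    edges: list[tuple[int, int]]
    factor: float = 0.7

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("effect factor must be > 0")

    @property
    def direction(self) -> str:
        return "decrease" if self.factor < 1 else (
            "increase" if self.factor > 1 else "null")


@dataclass
class SimulationConfig:
    """Generative settings for one synthetic cohort.

    The weight scale (``weight_mu`` about exp(-9.7) ~ 6e-5) makes the
    volume- and length-corrected weights consistent with a whole-brain
    streamline budget of a few thousand when converted back to counts.
    """

    seed: int
    n_controls: int = 27
    n_patients: int = 14
    n_nodes: int = 82
    backbone: str = "small_world"        # or "uniform_random"
    k_neighbors: int = 8
    rewire_prob: float = 0.1
    density: float = 0.1                 # uniform_random backbone only
    weight_mu: float = -9.7              # log-scale location of edge weights
    weight_sigma: float = 0.6
    noise_sigma: float = 0.2             # subject-level multiplicative noise
    effects: list[EffectSpec] = field(default_factory=list)
    age_mean_control: float = 25.0
    age_sd_control: float = 4.0
    age_mean_patient: float = 27.4
    age_sd_patient: float = 7.0
    female_fraction: float = 0.56

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if min(self.n_controls, self.n_patients, self.n_nodes) < 1:
            raise ValueError("cohort and node counts must be positive")
        if self.backbone not in ("small_world", "uniform_random"):
            raise ValueError(f"unknown backbone {self.backbone!r}")


@dataclass
class GroundTruth:
    """Exact record of what was planted, for recovery scoring."""

    backbone_weights: np.ndarray
    effects: list[EffectSpec]

    @property
    def effect_edges(self) -> list[tuple[int, int]]:
        return [tuple(sorted(e)) for spec in self.effects for e in spec.edges]


def select_connected_edges(weights: np.ndarray, n_edges: int,
                           rng: np.random.Generator) -> list[tuple[int, int]]:
    """Pick a random connected ``n_edges``-edge subgraph of a backbone.

    Grows an edge set from a random seed edge, repeatedly adding an edge
    incident to the current node set.
    """
    g = nx.from_numpy_array(weights > 0)
    all_edges = list(g.edges())
    if n_edges > len(all_edges):
        raise ValueError("backbone has too few edges")
    first = all_edges[rng.integers(len(all_edges))]
    chosen = [tuple(sorted(first))]
    nodes = set(first)
    while len(chosen) < n_edges:
        frontier = [
            tuple(sorted((u, v)))
            for u in nodes for v in g.neighbors(u)
            if tuple(sorted((u, v))) not in chosen
        ]
        if not frontier:
            raise ValueError("connected edge set exhausted the component")
        e = frontier[rng.integers(len(frontier))]
        chosen.append(e)
        nodes.update(e)
    return chosen


def _backbone_topology(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    seed = int(rng.integers(2**31 - 1))
    if cfg.backbone == "small_world":
        g = nx.watts_strogatz_graph(cfg.n_nodes, cfg.k_neighbors,
                                    cfg.rewire_prob, seed=seed)
    else:
        g = nx.gnp_random_graph(cfg.n_nodes, cfg.density, seed=seed)
    adj = np.zeros((cfg.n_nodes, cfg.n_nodes), dtype=bool)
    for u, v in g.edges():
        adj[u, v] = adj[v, u] = True
    return adj


def _atlas_for(n_nodes: int) -> Atlas:
    if n_nodes == 82:
        return load_default_atlas()
    from .atlas import AtlasNode

    # generic labels for non-default sizes; hemisphere split is nominal
    return Atlas(
        AtlasNode(i, f"Region {i}", f"N{i}", "L" if i < (n_nodes + 1) // 2 else "R",
                  "cortical") for i in range(n_nodes)
    )


def simulate_cohort(cfg: SimulationConfig):
    """Draw one cohort of weighted connectomes plus design and ground truth.

    Returns
    -------
    (connectomes, design, truth) : connectomes are ordered controls first
    then patients, matching the design rows. Identical seeds reproduce the
    cohort bit-exactly.

    Raises
    ------
    ValueError
        If a requested effect edge is absent from the backbone.
    """
    rng = np.random.default_rng(cfg.seed)
    atlas = _atlas_for(cfg.n_nodes)
    adj = _backbone_topology(cfg, rng)
    iu, ju = np.nonzero(np.triu(adj, 1))
    m = len(iu)
    backbone = np.zeros((cfg.n_nodes, cfg.n_nodes))
    base_w = rng.lognormal(cfg.weight_mu, cfg.weight_sigma, size=m)
    backbone[iu, ju] = base_w
    backbone = backbone + backbone.T

    effect_mult = np.ones((cfg.n_nodes, cfg.n_nodes))
    for spec in cfg.effects:
        for i, j in spec.edges:
            if not adj[i, j]:
                raise ValueError(f"effect edge ({i}, {j}) is not in the backbone")
            effect_mult[i, j] *= spec.factor
            effect_mult[j, i] *= spec.factor

    n_total = cfg.n_controls + cfg.n_patients
    group = np.concatenate([np.zeros(cfg.n_controls), np.ones(cfg.n_patients)])
    connectomes = []
    for s in range(n_total):
        noise = np.zeros_like(backbone)
        noise[iu, ju] = rng.lognormal(0.0, cfg.noise_sigma, size=m)
        noise = noise + noise.T
        w = backbone * noise
        if group[s] == 1:
            w = w * effect_mult
        prefix = "ctrl" if group[s] == 0 else "pat"
        k = s if group[s] == 0 else s - cfg.n_controls
        connectomes.append(
            Connectome(atlas=atlas, weights=w, subject_id=f"{prefix}{k:03d}")
        )

    age = np.concatenate([
        rng.normal(cfg.age_mean_control, cfg.age_sd_control, cfg.n_controls),
        rng.normal(cfg.age_mean_patient, cfg.age_sd_patient, cfg.n_patients),
    ]).clip(18, 65).round(1)
    sex = (rng.random(n_total) < cfg.female_fraction).astype(float)
    design = CohortDesign(
        subject_ids=[c.subject_id for c in connectomes],
        group=group, age=age, sex=sex,
    )
    truth = GroundTruth(backbone_weights=backbone, effects=list(cfg.effects))
    return connectomes, design, truth


def simulate_streamline_summary(
    connectome: Connectome,
    rng=None,
    length_range: tuple[float, float] = (20.0, 120.0),
    volume_mu: float = np.log(7000.0),
    volume_sigma: float = 0.25,
) -> StreamlineSummary:
    """Invert a connectome into plausible tractography summaries.

    Draws ROI volumes (log-normal around 7000 mm^3) and pair mean fiber
    lengths (uniform 20-120 mm), then sets integer streamline counts so
    that the length/volume-corrected reconstruction reproduces the input
    weights up to count rounding. Weights whose implied count rounds below
    one yield absent connections; implied counts below the construction
    threshold of three are reconstructed as zero by design.
    """
    rng = np.random.default_rng(rng)
    w = connectome.weights
    n = w.shape[0]
    volumes = rng.lognormal(volume_mu, volume_sigma, size=n)
    lengths = np.full((n, n), np.nan)
    iu, ju = np.triu_indices(n, k=1)
    pair_len = rng.uniform(*length_range, size=len(iu))
    lengths[iu, ju] = pair_len
    lengths[ju, iu] = pair_len
    vsum = volumes[:, None] + volumes[None, :]
    counts = np.rint(w * lengths * vsum / 2.0)
    counts = np.nan_to_num(counts, nan=0.0).astype(int)
    np.fill_diagonal(counts, 0)
    lengths[counts == 0] = np.nan
    return StreamlineSummary(counts=counts, mean_lengths=lengths,
                             volumes=volumes, subject_id=connectome.subject_id)
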