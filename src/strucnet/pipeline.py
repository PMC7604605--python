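"""End-to-end pipeline: cohort -> metrics -> group inference -> NBS -> hubs.

All randomness fans out from one user seed via numpy SeedSequence spawning,
so a config + seed pair reproduces every output table byte-for-byte. Each
output directory gets a machine-readable manifest (version, seed, config
echo, config hash).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import CohortDesign, load_default_atlas
from .hubs import identify_hubs
from .inference import nodal_comparison, permutation_glm
from .io import read_cohort, read_connectome_table, write_connectome
from .metrics import GraphMetrics
from .nbs import nbs_compare
from .simulate import EffectSpec, SimulationConfig, select_connected_edges, simulate_cohort
from .smallworld import SmallWorldness

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

GLOBAL_TESTED = ("global_efficiency", "local_efficiency",
                 "clustering_coefficient", "characteristic_path_length", "sigma")
NODAL_TESTED = ("strength", "nodal_efficiency", "clustering", "betweenness",
                "vulnerability")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Either ``connectome_dir`` + ``cohort_file`` point at existing data, or
    ``simulate`` holds keyword arguments for
    :class:`~strucnet.simulate.SimulationConfig` (plus optional
    ``n_effect_edges``/``effect_factor`` to auto-plant a connected effect).
    """

    out_dir: str
    seed: int
    connectome_dir: str | None = None
    cohort_file: str | None = None
    simulate: dict | None = None
    n_perm: int = 10000
    alpha: float = 0.05
    initial_p: tuple = (0.005, 0.05)
    n_random: int = 100
    compute_smallworld: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(cfg: RunConfig, rng: np.random.Generator):
    if cfg.simulate is not None:
        sim_kwargs = dict(cfg.simulate)
        n_effect = sim_kwargs.pop("n_effect_edges", 0)
        factor = sim_kwargs.pop("effect_factor", 0.7)
        sim_kwargs.setdefault("seed", int(rng.integers(2**31 - 1)))
        sim_cfg = SimulationConfig(**sim_kwargs)
        if n_effect:
            probe, _, _ = simulate_cohort(sim_cfg)
            edges = select_connected_edges(
                (probe[0].weights > 0), n_effect,
                np.random.default_rng(int(rng.integers(2**31 - 1))),
            )
            sim_cfg.effects = list(sim_cfg.effects) + [
                EffectSpec(edges=edges, factor=factor)
            ]
        connectomes, design, truth = simulate_cohort(sim_cfg)
        return connectomes, design, truth
    if cfg.connectome_dir is None or cfg.cohort_file is None:
        raise PipelineError(
            "input: config must provide either 'simulate' or both "
            "'connectome_dir' and 'cohort_file'"
        )
    cohort_path = Path(cfg.cohort_file)
    conn_dir = Path(cfg.connectome_dir)
    if not cohort_path.exists():
        raise PipelineError(f"input: cohort file {cohort_path} does not exist")
    if not conn_dir.is_dir():
        raise PipelineError(f"input: connectome dir {conn_dir} does not exist")
    design = read_cohort(cohort_path)
    atlas = load_default_atlas()
    connectomes = []
    for sid in design.subject_ids:
        p = conn_dir / f"{sid}.tsv"
        if not p.exists():
            raise PipelineError(f"input: missing connectome file {p}")
        connectomes.append(read_connectome_table(p, atlas, subject_id=sid))
    return connectomes, design, None


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage and write the result bundle under ``cfg.out_dir``.

    Returns the output directory. Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).spawn(6)
    rngs = [np.random.default_rng(s) for s in seeds]

    connectomes, design, truth = _load_inputs(cfg, rngs[0])
    design.to_frame().to_csv(out / "cohort.tsv", sep="\t", index=False)
    if cfg.simulate is not None:
        conn_dir = out / "connectomes"
        conn_dir.mkdir(exist_ok=True)
        for c in connectomes:
            write_connectome(c, conn_dir / f"{c.subject_id}.tsv")

    try:
        metrics = GraphMetrics().transform(connectomes)
        metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)
    except Exception as e:                             # pragma: no cover
        raise PipelineError(f"metrics: {e}") from e

    sw = None
    if cfg.compute_smallworld:
        try:
            sw = SmallWorldness(n_random=cfg.n_random,
                                random_state=rngs[1]).transform(connectomes)
            sw.to_csv(out / "smallworld.tsv", sep="\t", index=False)
        except Exception as e:
            raise PipelineError(f"smallworld: {e}") from e

    try:
        rows = []
        glob = metrics[metrics["node"] == "GLOBAL"].pivot(
            index="subject_id", columns="metric", values="value"
        ).loc[list(design.subject_ids)]
        if sw is not None:
            glob = glob.join(sw.set_index("subject_id")[["sigma"]])
        for metric in GLOBAL_TESTED:
            if metric not in glob.columns:
                continue
            res = permutation_glm(glob[metric].to_numpy(), design,
                                  n_perm=cfg.n_perm,
                                  seed=rngs[2].integers(2**31 - 1))
            for tail, r in res.items():
                rows.append((metric, tail, r.observed_stat, r.p_uncorrected))
        pd.DataFrame(rows, columns=["metric", "tail", "t_observed",
                                    "p_uncorrected"]).to_csv(
            out / "global_comparison.tsv", sep="\t", index=False)
    except Exception as e:
        raise PipelineError(f"global_comparison: {e}") from e

    try:
        nodal = metrics[metrics["node"] != "GLOBAL"]
        frames = []
        for metric in NODAL_TESTED:
            table = nodal[nodal["metric"] == metric].pivot(
                index="subject_id", columns="node", values="value"
            ).loc[list(design.subject_ids)]
            df = nodal_comparison(table, design, n_perm=cfg.n_perm,
                                  seed=rngs[3].integers(2**31 - 1))
            df.insert(0, "metric", metric)
            frames.append(df)
        pd.concat(frames).to_csv(out / "nodal_comparison.tsv", sep="\t",
                                 index=False)
    except Exception as e:
        raise PipelineError(f"nodal_comparison: {e}") from e

    try:
        for p0 in cfg.initial_p:
            comps = nbs_compare(connectomes, design, initial_p=p0,
                                n_perm=cfg.n_perm, alpha=cfg.alpha,
                                seed=rngs[4].integers(2**31 - 1))
            payload = {d: [c.to_dict() for c in lst] for d, lst in comps.items()}
            with open(out / f"nbs_p{p0:g}.json", "w") as fh:
                json.dump(payload, fh, indent=2)
    except Exception as e:
        raise PipelineError(f"nbs: {e}") from e

    try:
        bt = nodal[nodal["metric"] == "betweenness"].pivot(
            index="subject_id", columns="node", values="value")
        st = nodal[nodal["metric"] == "strength"].pivot(
            index="subject_id", columns="node", values="value")
        for gname, gval in (("controls", 0), ("patients", 1)):
            ids = [s for s, g in zip(design.subject_ids, design.group) if g == gval]
            identify_hubs(bt.loc[ids], st.loc[ids]).to_csv(
                out / f"hubs_{gname}.tsv", sep="\t", index=False)
    except Exception as e:
        raise PipelineError(f"hubs: {e}") from e

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "n_subjects": design.n_subjects,
        "planted_effect_edges": (
            [list(e) for e in truth.effect_edges] if truth is not None else None
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
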