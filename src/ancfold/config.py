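"""Run configuration and end-to-end pipeline orchestration.

A run is described by one YAML file holding every tunable of every stage;
unknown keys are rejected so typos fail loudly.  ``run_pipeline`` executes
sample -> connect -> analyze and writes a directory of text artifacts
(conformations, roadmap JSON, attempt log, pathways, SSFO and method
reports, plus a machine-readable manifest).  A fixed config + seed yields
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import yaml

from . import __version__
from .anc import History, AttemptRecord
from .energy import EnergyModel
from .fixtures import ToySpec, make_toy_protein
from .protein_model import ProteinTopology, read_native_pdb, write_conformations
from .roadmap import (BuildConfig, Roadmap, dominant_order, orders_agree,
                      extract_folding_pathways, method_report,
                      ssfo_distribution, build_until_stable)
from .sampling import SamplerConfig, open_chain_energy

__all__ = ["RunConfig", "load_config", "run_pipeline", "build_topology",
           "build_energy_model", "write_attempt_log", "read_attempt_log"]


@dataclass
class RunConfig:
    # inputs
    pdb: Optional[str] = None
    toy_n: int = 8
    toy_segments: Tuple[Tuple[str, str, int, int], ...] = (("a1", "helix", 0, 5),)
    toy_seed: int = 3
    # strategy
    strategy: str = "anc-local"
    k: int = 20
    nf_local: int = 40
    gamma: float = 0.1
    alpha: float = 0.5
    # energy model
    kT: float = 1.0
    clash_sampling: float = 2.4
    clash_connect: float = 1.0
    hp_cutoff: float = 6.0
    hp_energy: float = -1.0
    e_max_factor: float = 2.0
    # planner / sampler
    resolution: float = 5.0
    perturb_magnitude: float = 30.0
    torsions_per_move: int = 4
    max_attempts: int = 10000
    # construction loop
    batch: int = 20
    max_batches: int = 8
    stability_threshold: float = 30.0
    unfolded_fraction: float = 0.1
    # run
    seed: int = 0
    experimental_order: Optional[str] = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["toy_segments"] = [list(s) for s in self.toy_segments]
        return d


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "toy_segments" in raw:
        raw["toy_segments"] = tuple(tuple(s) for s in raw["toy_segments"])
    return RunConfig(**raw)


def build_energy_model(cfg: RunConfig) -> EnergyModel:
    return EnergyModel(clash_sampling=cfg.clash_sampling,
                       clash_connect=cfg.clash_connect,
                       hp_cutoff=cfg.hp_cutoff, hp_energy=cfg.hp_energy,
                       kT=cfg.kT)


def build_topology(cfg: RunConfig,
                   model: Optional[EnergyModel] = None) -> ProteinTopology:
    if cfg.pdb:
        return read_native_pdb(cfg.pdb)
    spec = ToySpec(n=cfg.toy_n, segments=tuple(cfg.toy_segments),
                   seed=cfg.toy_seed)
    return make_toy_protein(spec, model=model)


def write_attempt_log(path, history: History) -> None:
    with open(path, "w") as fh:
        fh.write("step\tnode\tmethod\tsuccess\tedge_weight\treward\tcost\n")
        for r in history.records:
            fh.write(f"{r.step}\t{r.node_id}\t{r.method_id}\t{int(r.success)}\t"
                     f"{r.edge_weight!r}\t{r.reward!r}\t{r.cost!r}\n")


def read_attempt_log(path) -> History:
    history = History()
    with open(path) as fh:
        next(fh)
        for line in fh:
            step, node, method, success, y, reward, cost = line.rstrip("\n").split("\t")
            history._step = int(step) - 1
            history.append(AttemptRecord(
                node_id=node, method_id=method, reward=float(reward),
                cost=float(cost), step=int(step), success=bool(int(success)),
                edge_weight=float(y)))
    return history


def _write_selections(path, rm: Roadmap) -> None:
    with open(path, "w") as fh:
        fh.write("node\tmethod\n")
        for node, mid in rm.selections:
            fh.write(f"{node}\t{mid}\n")


def _write_ssfo(path, dist, experimental: Optional[str]) -> None:
    lines = ["ordering\tpercent"]
    for order, pct in sorted(dist.percentages.items(),
                             key=lambda kv: (-kv[1], kv[0])):
        lines.append(f"{','.join(order)}\t{pct!r}")
    lines.append(f"# pathway_count\t{dist.pathway_count}")
    if dist.pathway_count:
        dom = dominant_order(dist)
        lines.append(f"# dominant\t{','.join(dom)}")
        if experimental:
            lines.append(f"# agrees_with_experimental\t"
                         f"{orders_agree(dom, experimental)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def run_pipeline(cfg: RunConfig, out_dir) -> dict:
    """Execute the full sample -> connect -> analyze pipeline.

    Returns a summary dict (also written as ``manifest.json``); all other
    artifacts land in ``out_dir`` as plain text.
    """
    os.makedirs(out_dir, exist_ok=True)
    model = build_energy_model(cfg)
    topo = build_topology(cfg, model=model)
    if not cfg.pdb:
        from .protein_model import write_pdb
        write_pdb(os.path.join(out_dir, "native.pdb"), topo,
                  [topo.native_conformation()])

    e_min = open_chain_energy(topo, model)
    sampler = SamplerConfig(E_min=e_min, E_max=cfg.e_max_factor * e_min,
                            max_attempts=cfg.max_attempts,
                            perturb_magnitude=cfg.perturb_magnitude,
                            torsions_per_move=cfg.torsions_per_move,
                            rng_seed=cfg.seed)
    bcfg = BuildConfig(strategy=cfg.strategy, batch=cfg.batch,
                       max_batches=cfg.max_batches,
                       stability_threshold=cfg.stability_threshold,
                       k=cfg.k, nf_local=cfg.nf_local, gamma=cfg.gamma,
                       alpha=cfg.alpha, resolution=cfg.resolution,
                       unfolded_fraction=cfg.unfolded_fraction,
                       seed=cfg.seed, sampler=sampler)
    rm = build_until_stable(topo, model, bcfg)

    write_conformations(os.path.join(out_dir, "conformations.txt"),
                        [rm.nodes[cid] for cid in sorted(rm.nodes)])
    with open(os.path.join(out_dir, "roadmap.json"), "w") as fh:
        fh.write(rm.to_json())
    write_attempt_log(os.path.join(out_dir, "attempts.tsv"), rm.history)
    _write_selections(os.path.join(out_dir, "selections.tsv"), rm)

    pathways = extract_folding_pathways(rm)
    with open(os.path.join(out_dir, "pathways.txt"), "w") as fh:
        for path, weight in pathways:
            fh.write(f"{weight!r}\t{' '.join(path)}\n")
    dist = ssfo_distribution(topo, model, rm, pathways)
    _write_ssfo(os.path.join(out_dir, "ssfo.tsv"), dist,
                cfg.experimental_order)
    report = method_report(rm, pathways)
    with open(os.path.join(out_dir, "method_report.tsv"), "w") as fh:
        fh.write(report.to_tsv())

    summary = {
        "version": __version__,
        "config": cfg.to_dict(),
        "e_min": e_min,
        "stable": rm.stable,
        "batches_run": rm.batches_run,
        "n_nodes": len(rm.nodes),
        "n_edges": rm.graph.number_of_edges(),
        "n_pathways": len(pathways),
        "pathway_quality": report.pathway_quality,
        "energy_calls": model.call_counter,
        "dominant_order": list(dominant_order(dist)) if dist.pathway_count else None,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
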