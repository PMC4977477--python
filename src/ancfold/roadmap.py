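"""Roadmap assembly, folding-pathway extraction and evaluation metrics.

The roadmap is a directed weighted graph over conformations.  Construction
alternates sampling and connection in batches until the distribution of
secondary-structure formation orders (SSFO) along the extracted folding
pathways stabilizes: the build stops when no ordering's share changes by
more than the stability threshold (30 percentage points) between successive
batches.

Folding pathways are minimum-weight directed paths from each unfolded state
(the top decile of node energies, the model's stand-in for the denatured
ensemble) to the native state; since edge weights are -log transition
probabilities, these are the most energetically feasible transitions.

A segment counts as *formed* at the first conformation along a pathway at
which at least 70 % of its native hydrogen bonds are satisfied (current
length within 110 % of native); the SSFO of a pathway orders segments by
that formation point.
"""

from __future__ import annotations

import json
import heapq
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import networkx as nx

from .anc import (AttemptRecord, BanditState, ConnectionMethod, ConnectResult,
                  History, connect_node_global, connect_node_local,
                  roadmap_attempt_executor)
from .energy import EnergyModel, forward_kinematics
from .local_planner import DEFAULT_RESOLUTION
from .metrics import METRIC_NAMES, make_metric
from .protein_model import Conformation, ProteinTopology
from .rigidity import HBOND_SATISFIED_FACTOR
from .sampling import SamplerConfig, extend_samples, open_chain_energy

__all__ = ["Roadmap", "SSFODistribution", "MethodReport", "BuildConfig",
           "build_until_stable", "extract_folding_pathways", "ssfo_of_path",
           "dominant_order", "pathway_quality", "method_report",
           "segment_formation_fractions", "STRATEGIES", "RoadmapError"]

STRATEGIES = ("anc-local", "anc-global") + METRIC_NAMES
FORMATION_FRACTION = 0.70
UNFOLDED_FRACTION = 0.10
DEFAULT_STABILITY_THRESHOLD = 30.0  # percentage points


class RoadmapError(RuntimeError):
    pass


@dataclass
class Roadmap:
    """Weighted directed graph of conformations with edge provenance."""

    topo: ProteinTopology
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    nodes: Dict[str, Conformation] = field(default_factory=dict)
    native_id: str = "native"
    unfolded_ids: Tuple[str, ...] = ()
    history: History = field(default_factory=History)
    selections: List[Tuple[str, str]] = field(default_factory=list)
    stable: bool = False
    batches_run: int = 0
    ssfo_trace: List["SSFODistribution"] = field(default_factory=list)

    def add_node(self, conf: Conformation) -> None:
        if conf.id in self.nodes:
            raise ValueError(f"duplicate conformation id {conf.id!r}")
        self.nodes[conf.id] = conf
        self.graph.add_node(conf.id)

    def add_edge(self, u: str, v: str, weight: float, method_id: str,
                 step: int) -> None:
        if u == v:
            raise ValueError("self-loops are not allowed")
        if not (math.isfinite(weight) and weight >= 0):
            raise ValueError("edge weights must be finite and non-negative")
        if self.graph.has_edge(u, v) and self.graph[u][v]["weight"] <= weight:
            return
        self.graph.add_edge(u, v, weight=weight, method=method_id, step=step)

    def refresh_unfolded(self, fraction: float = UNFOLDED_FRACTION) -> None:
        """Flag the top energy decile (minimum 1 node) as the unfolded set."""
        scored = sorted(((c.energy, cid) for cid, c in self.nodes.items()
                         if cid != self.native_id and c.energy is not None
                         and math.isfinite(c.energy)), reverse=True)
        if not scored:
            self.unfolded_ids = ()
            return
        count = max(1, int(round(fraction * len(scored))))
        self.unfolded_ids = tuple(sorted(cid for _, cid in scored[:count]))

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "native_id": self.native_id,
            "unfolded_ids": list(self.unfolded_ids),
            "stable": self.stable,
            "batches_run": self.batches_run,
            "nodes": {
                cid: {"torsions": [repr(float(t)) for t in conf.torsions],
                      "energy": None if conf.energy is None
                      else repr(float(conf.energy)),
                      "rigidity": None if conf.rigidity_map is None
                      else [int(x) for x in conf.rigidity_map.labels]}
                for cid, conf in sorted(self.nodes.items())
            },
            "edges": [
                {"u": u, "v": v, "weight": repr(float(d["weight"])),
                 "method": d["method"], "step": d["step"]}
                for u, v, d in sorted(self.graph.edges(data=True))
            ],
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str, topo: ProteinTopology) -> "Roadmap":
        payload = json.loads(text)
        rm = cls(topo=topo, native_id=payload["native_id"],
                 unfolded_ids=tuple(payload["unfolded_ids"]),
                 stable=payload["stable"], batches_run=payload["batches_run"])
        for cid, nd in payload["nodes"].items():
            conf = Conformation(
                torsions=np.array([float(t) for t in nd["torsions"]]), id=cid,
                energy=None if nd["energy"] is None else float(nd["energy"]))
            rm.add_node(conf)
        for e in payload["edges"]:
            rm.add_edge(e["u"], e["v"], float(e["weight"]), e["method"],
                        e["step"])
        return rm


@dataclass(frozen=True)
class SSFODistribution:
    """Share (percent) of pathways following each formation-order tuple."""

    percentages: Dict[Tuple[str, ...], float]
    pathway_count: int

    def __post_init__(self):
        if self.pathway_count > 0:
            total = sum(self.percentages.values())
            if abs(total - 100.0) > 1e-6:
                raise ValueError(f"percentages sum to {total}, not 100")


def max_shift(a: SSFODistribution, b: SSFODistribution) -> float:
    """Largest absolute per-ordering percentage change between two
    distributions (orderings absent from one side count at 0 %)."""
    keys = set(a.percentages) | set(b.percentages)
    if not keys:
        return 0.0
    return max(abs(a.percentages.get(k, 0.0) - b.percentages.get(k, 0.0))
               for k in keys)


@dataclass(frozen=True)
class MethodReport:
    usage_percent: Dict[str, float]
    success_rate: Dict[str, float]
    total_cost: Dict[str, float]
    attempts: Dict[str, int]
    pathway_quality: float
    n_pathways: int

    def to_tsv(self) -> str:
        lines = ["method\tusage_percent\tsuccess_rate\tattempts\ttotal_cost"]
        for mid in sorted(self.usage_percent):
            lines.append(f"{mid}\t{self.usage_percent[mid]:.4f}\t"
                         f"{self.success_rate[mid]:.6f}\t{self.attempts[mid]}\t"
                         f"{self.total_cost[mid]:.1f}")
        lines.append(f"# pathway_quality\t{self.pathway_quality!r}")
        lines.append(f"# n_pathways\t{self.n_pathways}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Pathway extraction (deterministic Dijkstra)
# ---------------------------------------------------------------------------

def _dijkstra_path(graph: nx.DiGraph, source: str, target: str) -> Optional[Tuple[List[str], float]]:
    """Minimum-weight path with deterministic lexicographic tie-breaking."""
    dist = {source: 0.0}
    parent: Dict[str, Optional[str]] = {source: None}
    done = set()
    heap = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        if u == target:
            break
        for v, data in sorted(graph[u].items()):
            nd = d + data["weight"]
            if v not in dist or nd < dist[v] - 1e-15:
                dist[v] = nd
                parent[v] = u
                heapq.heappush(heap, (nd, v))
            elif abs(nd - dist[v]) <= 1e-15 and v not in done:
                if parent[v] is not None and u < parent[v]:
                    parent[v] = u
    if target not in done:
        return None
    path = [target]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    path.reverse()
    return path, dist[target]


def extract_folding_pathways(rm: Roadmap) -> List[Tuple[List[str], float]]:
    """Minimum-weight directed path from every unfolded state to the native
    state; unreachable unfolded states are skipped."""
    if rm.native_id not in rm.nodes:
        raise RoadmapError("roadmap has no native node")
    pathways = []
    for uid in rm.unfolded_ids:
        res = _dijkstra_path(rm.graph, uid, rm.native_id)
        if res is not None:
            pathways.append(res)
    return pathways


# ---------------------------------------------------------------------------
# Secondary-structure formation order
# ---------------------------------------------------------------------------

def _segment_hbonds(topo: ProteinTopology, model: EnergyModel) -> Dict[str, list]:
    """Native hydrogen bonds supporting each segment (a bond supports every
    segment containing one of its endpoint residues)."""
    cons = model.constraints(topo)
    per_segment: Dict[str, list] = {seg.label: [] for seg in topo.native_segments}
    for (a, b), role, d_nat in zip(cons.pairs, cons.roles, cons.native_lengths):
        if role != "hbond":
            continue
        ra, rb = a // 6, b // 6
        for seg in topo.native_segments:
            if ra in seg.residues or rb in seg.residues:
                per_segment[seg.label].append((a, b, float(d_nat)))
    return per_segment


def segment_formation_fractions(topo: ProteinTopology, model: EnergyModel,
                                conf: Conformation) -> Dict[str, float]:
    """Fraction of each segment's native hydrogen bonds currently satisfied."""
    per_segment = _segment_hbonds(topo, model)
    coords = forward_kinematics(topo, conf).coords
    out = {}
    for label, bonds in per_segment.items():
        if not bonds:
            out[label] = 0.0
            continue
        ok = sum(1 for a, b, d_nat in bonds
                 if np.linalg.norm(coords[a] - coords[b])
                 <= HBOND_SATISFIED_FACTOR * d_nat)
        out[label] = ok / len(bonds)
    return out


def ssfo_of_path(topo: ProteinTopology, model: EnergyModel,
                 path_confs: Sequence[Conformation]) -> Tuple[str, ...]:
    """Formation-order tuple of a pathway walked unfolded -> native.

    Each segment forms at the first conformation with >= 70 % of its native
    hydrogen bonds satisfied; ties resolve to native (sequence) order and
    never-formed segments are appended last in native order.
    """
    if not topo.native_segments:
        raise RoadmapError("topology declares no native segments")
    labels = [seg.label for seg in topo.native_segments]
    formed_at = {label: None for label in labels}
    for idx, conf in enumerate(path_confs):
        fracs = segment_formation_fractions(topo, model, conf)
        for label in labels:
            if formed_at[label] is None and fracs[label] >= FORMATION_FRACTION:
                formed_at[label] = idx
    native_rank = {label: i for i, label in enumerate(labels)}
    formed = sorted((label for label in labels if formed_at[label] is not None),
                    key=lambda s: (formed_at[s], native_rank[s]))
    never = [label for label in labels if formed_at[label] is None]
    return tuple(formed + never)


def ssfo_distribution(topo: ProteinTopology, model: EnergyModel, rm: Roadmap,
                      pathways: Sequence[Tuple[List[str], float]]) -> SSFODistribution:
    counts: Dict[Tuple[str, ...], int] = {}
    for path, _ in pathways:
        order = ssfo_of_path(topo, model, [rm.nodes[cid] for cid in path])
        counts[order] = counts.get(order, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return SSFODistribution(percentages={}, pathway_count=0)
    return SSFODistribution(
        percentages={k: 100.0 * v / total for k, v in counts.items()},
        pathway_count=total)


def dominant_order(dist: SSFODistribution) -> Tuple[str, ...]:
    """Ordering with the greatest pathway share; lexicographic tie-break."""
    if dist.pathway_count == 0 or not dist.percentages:
        raise RoadmapError("empty formation-order distribution")
    best = max(dist.percentages.values())
    tied = sorted(k for k, v in dist.percentages.items() if v == best)
    return tied[0]


def orders_agree(order: Tuple[str, ...], experimental: str) -> bool:
    """Case-insensitive exact tuple match against 'b1,b2,a1'-style strings."""
    exp = tuple(s.strip().lower() for s in experimental.split(",") if s.strip())
    return tuple(s.lower() for s in order) == exp


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------

def pathway_quality(rm: Roadmap,
                    pathways: Sequence[Tuple[List[str], float]]) -> float:
    """Sum over edges of weight x (number of pathways traversing the edge);
    lower is better.  Edges on no pathway contribute nothing."""
    dominance: Dict[Tuple[str, str], int] = {}
    for path, _ in pathways:
        for u, v in zip(path[:-1], path[1:]):
            dominance[(u, v)] = dominance.get((u, v), 0) + 1
    return float(sum(rm.graph[u][v]["weight"] * dom
                     for (u, v), dom in dominance.items()))


def method_report(rm: Roadmap,
                  pathways: Optional[Sequence] = None) -> MethodReport:
    """Per-method usage, local-planner success rate and cumulative cost."""
    if pathways is None:
        pathways = extract_folding_pathways(rm)
    attempts: Dict[str, int] = {}
    successes: Dict[str, int] = {}
    cost: Dict[str, float] = {}
    for rec in rm.history.records:
        attempts[rec.method_id] = attempts.get(rec.method_id, 0) + 1
        successes[rec.method_id] = successes.get(rec.method_id, 0) + int(rec.success)
        cost[rec.method_id] = cost.get(rec.method_id, 0.0) + rec.cost
    usage_counts: Dict[str, int] = {}
    for _, mid in rm.selections:
        usage_counts[mid] = usage_counts.get(mid, 0) + 1
    total_sel = sum(usage_counts.values())
    method_ids = sorted(set(attempts) | set(usage_counts))
    return MethodReport(
        usage_percent={mid: (100.0 * usage_counts.get(mid, 0) / total_sel
                             if total_sel else 0.0) for mid in method_ids},
        success_rate={mid: (successes.get(mid, 0) / attempts[mid]
                            if attempts.get(mid) else 0.0) for mid in method_ids},
        total_cost={mid: cost.get(mid, 0.0) for mid in method_ids},
        attempts={mid: attempts.get(mid, 0) for mid in method_ids},
        pathway_quality=pathway_quality(rm, pathways),
        n_pathways=len(pathways))


# ---------------------------------------------------------------------------
# Construction loop
# ---------------------------------------------------------------------------

@dataclass
class BuildConfig:
    strategy: str = "anc-local"
    batch: int = 25
    max_batches: int = 12
    stability_threshold: float = DEFAULT_STABILITY_THRESHOLD  # percentage points
    k: int = 20
    nf_local: int = 40
    gamma: float = 0.1
    alpha: float = 0.5
    resolution: float = DEFAULT_RESOLUTION
    unfolded_fraction: float = UNFOLDED_FRACTION
    seed: int = 0
    sampler: Optional[SamplerConfig] = None

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.batch < 1:
            raise ValueError("batch must be >= 1")


def _methods_for(cfg: BuildConfig, topo: ProteinTopology,
                 model: EnergyModel) -> List[ConnectionMethod]:
    names = METRIC_NAMES if cfg.strategy in ("anc-local", "anc-global") \
        else (cfg.strategy,)
    return [ConnectionMethod(id=name, metric=make_metric(name, topo, model),
                             k=cfg.k, resolution=cfg.resolution)
            for name in names]


def build_until_stable(topo: ProteinTopology, model: EnergyModel,
                       cfg: BuildConfig) -> Roadmap:
    """Alternate sampling and connection until the SSFO distribution is
    stable (per-ordering change <= threshold between successive batches).

    Raises RoadmapError when the iteration cap is hit with no
    unfolded-to-native pathway.
    """
    rng = np.random.default_rng(cfg.seed)
    sample_rng = np.random.default_rng(rng.integers(2 ** 31))
    select_rng = np.random.default_rng(rng.integers(2 ** 31))

    scfg = cfg.sampler or SamplerConfig(E_min=open_chain_energy(topo, model))
    rm = Roadmap(topo=topo)
    native = topo.native_conformation()
    from .energy import total_energy
    total_energy(topo, native, model, phase="sampling")
    rm.add_node(native)
    accepted = [native]

    methods = _methods_for(cfg, topo, model)
    global_state = BanditState(method_ids=[m.id for m in methods],
                               gamma=cfg.gamma, alpha=cfg.alpha)
    prev_dist: Optional[SSFODistribution] = None

    for batch_i in range(cfg.max_batches):
        new = extend_samples(topo, model, scfg, accepted, cfg.batch,
                             sample_rng, start_index=len(accepted))
        executor = roadmap_attempt_executor(rm.nodes, topo, model)
        for conf in new:
            rm.add_node(conf)
            if cfg.strategy == "anc-local":
                result = connect_node_local(conf, methods, rm.history,
                                            select_rng, executor,
                                            nf_local=cfg.nf_local,
                                            gamma=cfg.gamma, alpha=cfg.alpha)
            else:  # anc-global and single fixed methods share the global driver
                result = connect_node_global(conf, methods, global_state,
                                             rm.history, select_rng, executor)
            rm.selections.append((conf.id, result.method_id))
            for out, rec in zip(result.outcomes, result.records):
                if out.success:
                    rm.add_edge(conf.id, out.neighbor_id, out.forward_weight,
                                result.method_id, rec.step)
                    rm.add_edge(out.neighbor_id, conf.id, out.reverse_weight,
                                result.method_id, rec.step)
        rm.batches_run = batch_i + 1
        rm.refresh_unfolded(cfg.unfolded_fraction)
        pathways = extract_folding_pathways(rm)
        dist = ssfo_distribution(topo, model, rm, pathways)
        rm.ssfo_trace.append(dist)
        if prev_dist is not None and pathways:
            if max_shift(prev_dist, dist) <= cfg.stability_threshold:
                rm.stable = True
                return rm
        prev_dist = dist

    if not extract_folding_pathways(rm):
        raise RoadmapError(
            f"no unfolded-to-native pathway after {cfg.max_batches} batches "
            f"({len(rm.nodes)} nodes, {rm.graph.number_of_edges()} edges)")
    rm.stable = False  # explicit non-convergence: roadmap returned with flag
    return rm
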