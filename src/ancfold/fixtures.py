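"""Deterministic synthetic fixtures: toy proteins and bandit benches.

Everything here is generated in-process from a seed — no downloads, no
stored data files — so the full pipeline is exercisable on chains of 5-30
residues with declared native secondary structure.

Toy proteins place ideal Ramachandran torsions inside each declared
segment (helix phi = -57, psi = -47; strand phi = -119, psi = 113) and
seeded random torsions in the loops, regenerating the loops until the
native state is clash-free.

The two-region bench is a mock connection environment for studying method
locality: two mock connection methods whose success probabilities flip
between two regions of a fake torsion space.  It plugs into the bandit
drivers in place of real planners, isolating selection behaviour from
roadmap mechanics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .anc import (AttemptOutcome, BanditState, ConnectionMethod, History,
                  connect_node_global, connect_node_local)
from .energy import EnergyModel, clash_check
from .protein_model import (Conformation, ProteinTopology, Segment,
                            forward_kinematics, write_pdb)

__all__ = ["ToySpec", "make_toy_protein", "TwoRegionBench",
           "make_two_region_bench", "run_two_arm_bench",
           "run_localization_experiment", "IDEAL_TORSIONS"]

# Ideal secondary-structure dihedrals (degrees), standard Ramachandran values.
IDEAL_TORSIONS = {"helix": (-57.0, -47.0), "strand": (-119.0, 113.0)}

HYDROPHOBIC_RES = "LEU"
POLAR_RES = "SER"
MAX_NATIVE_TRIES = 1000


@dataclass(frozen=True)
class ToySpec:
    """Plan for a toy chain: size, segments, hydrophobic pattern, seed."""

    n: int
    segments: Tuple[Tuple[str, str, int, int], ...] = ()
    hydrophobic: Optional[Tuple[bool, ...]] = None
    seed: int = 0

    def __post_init__(self):
        if not 4 <= self.n <= 40:
            raise ValueError("toy chains span 4-40 residues")
        for label, kind, start, end in self.segments:
            if not (0 <= start < end <= self.n):
                raise ValueError(f"segment {label} does not fit in n={self.n}")


def _default_hydrophobic(n: int) -> Tuple[bool, ...]:
    # sparse periodic pattern: every third residue apolar
    return tuple(i % 3 == 0 for i in range(n))


def make_toy_protein(spec: ToySpec, pdb_path=None,
                     model: Optional[EnergyModel] = None) -> ProteinTopology:
    """Build a toy topology with ideal in-segment torsions and seeded random
    loops; the native state is guaranteed clash-free (loops are regenerated
    until it is).  Optionally writes the matching native PDB file."""
    rng = np.random.default_rng(spec.seed)
    model = model or EnergyModel()
    n = spec.n
    hydro = spec.hydrophobic or _default_hydrophobic(n)
    sequence = tuple(HYDROPHOBIC_RES if h else POLAR_RES for h in hydro)
    segments = tuple(Segment(label=l, kind=k, start=s, end=e)
                     for l, k, s, e in spec.segments)

    in_segment = np.zeros(2 * n, dtype=bool)
    torsions = np.full(2 * n, 180.0)
    for seg in segments:
        phi, psi = IDEAL_TORSIONS[seg.kind]
        for i in seg.residues:
            torsions[2 * i] = phi
            torsions[2 * i + 1] = psi
            in_segment[2 * i] = in_segment[2 * i + 1] = True
    # terminal dihedrals are undefined: force the 180 placeholder even when
    # a segment touches the chain ends
    torsions[0] = torsions[2 * n - 1] = 180.0
    in_segment[0] = in_segment[2 * n - 1] = True
    loop_idx = np.flatnonzero(~in_segment)

    topo = None
    for _ in range(MAX_NATIVE_TRIES):
        t = torsions.copy()
        t[loop_idx] = rng.uniform(-180.0, 180.0, size=loop_idx.size)
        candidate = ProteinTopology(sequence=sequence, hydrophobic=hydro,
                                    native_torsions=t,
                                    native_segments=segments)
        coords = forward_kinematics(candidate, candidate.native_conformation())
        if clash_check(candidate, coords, model, phase="sampling"):
            topo = candidate
            break
    if topo is None:
        raise RuntimeError(
            f"could not find a clash-free native in {MAX_NATIVE_TRIES} tries")
    if pdb_path is not None:
        write_pdb(pdb_path, topo, [topo.native_conformation()])
    return topo


# ---------------------------------------------------------------------------
# Bandit benches
# ---------------------------------------------------------------------------

@dataclass
class BenchQuery:
    """A mock query: a region label plus a point in a fake torsion space."""

    id: str
    region: int
    torsions: np.ndarray


@dataclass
class TwoRegionBench:
    """Mock connection environment with region-dependent method success.

    Method "cm_A" succeeds at ``p_high`` in region 0 and ``p_low`` in
    region 1; "cm_B" is the mirror image.  Successful attempts return an
    edge weight drawn uniformly from ``weight_range``; every attempt costs
    one energy call.
    """

    seed: int = 0
    p_high: float = 0.9
    p_low: float = 0.2
    attempts_per_query: int = 5
    dim: int = 4
    center_offset: float = 60.0
    position_noise: float = 10.0
    weight_range: Tuple[float, float] = (0.5, 1.5)
    methods: List[ConnectionMethod] = field(default_factory=lambda: [
        ConnectionMethod(id="cm_A"), ConnectionMethod(id="cm_B")])

    def success_probability(self, region: int, method_id: str) -> float:
        favored = "cm_A" if region == 0 else "cm_B"
        return self.p_high if method_id == favored else self.p_low

    def correct_method(self, region: int) -> str:
        return "cm_A" if region == 0 else "cm_B"

    def make_query(self, region: int, rng: np.random.Generator,
                   qid: str) -> BenchQuery:
        center = (-self.center_offset if region == 0 else self.center_offset)
        pos = center + rng.uniform(-self.position_noise, self.position_noise,
                                   size=self.dim)
        return BenchQuery(id=qid, region=region, torsions=pos)

    def executor(self):
        def attempt(q: BenchQuery, method: ConnectionMethod,
                    rng: np.random.Generator) -> List[AttemptOutcome]:
            p = self.success_probability(q.region, method.id)
            outcomes = []
            for j in range(self.attempts_per_query):
                ok = bool(rng.random() < p)
                y = float(rng.uniform(*self.weight_range)) if ok else math.inf
                outcomes.append(AttemptOutcome(
                    neighbor_id=f"{q.id}:{j}", success=ok, forward_weight=y,
                    reverse_weight=y, cost=1.0))
            return outcomes
        return attempt


def make_two_region_bench(seed: int = 0, **kwargs) -> TwoRegionBench:
    return TwoRegionBench(seed=seed, **kwargs)


def run_two_arm_bench(seed: int, steps: int = 500, p_good: float = 0.8,
                      p_bad: float = 0.2, gamma: float = 0.1,
                      alpha: float = 0.5) -> float:
    """Stationary two-armed sanity bench: Bernoulli rewards, unit costs.

    Feeds a single persistent bandit state ``steps`` selections and returns
    the empirical frequency with which the better arm was chosen.
    """
    rng = np.random.default_rng(seed)
    state = BanditState(method_ids=("good", "bad"), gamma=gamma, alpha=alpha)
    probs = {"good": p_good, "bad": p_bad}
    picks = {"good": 0, "bad": 0}
    from .anc import cost_adjusted_probability
    for _ in range(steps):
        p = cost_adjusted_probability(state)
        arm = state.method_ids[0] if rng.random() < p[0] else state.method_ids[1]
        picks[arm] += 1
        ok = rng.random() < probs[arm]
        # success: a nominal unit edge weight; failure: reward 0
        state.observe(arm, ok, 1.0, 1.0)
    return picks["good"] / steps


def run_localization_experiment(seed: int, n_queries: int = 120,
                                nf_local: int = 40, gamma: float = 0.1,
                                alpha: float = 0.5,
                                warmup: int = 40,
                                bench: Optional[TwoRegionBench] = None
                                ) -> Tuple[float, float]:
    """Paired comparison of ANC-local vs ANC-global on the two-region bench.

    The same seeded query stream (alternating regions) is played through
    both selection regimes; returns the post-warmup frequency with which
    each regime picked the region-correct method (local, global).
    """
    bench = bench or make_two_region_bench(seed)

    def play(local: bool) -> float:
        qrng = np.random.default_rng(seed)
        srng = np.random.default_rng(seed + 1)
        history = History()
        state = BanditState(method_ids=[m.id for m in bench.methods],
                            gamma=gamma, alpha=alpha)
        correct = total = 0
        executor = bench.executor()
        for t in range(n_queries):
            region = t % 2
            q = bench.make_query(region, qrng, f"q{t}")
            if local:
                res = connect_node_local(q, bench.methods, history, srng,
                                         executor, nf_local=nf_local,
                                         gamma=gamma, alpha=alpha)
            else:
                res = connect_node_global(q, bench.methods, state, history,
                                          srng, executor)
            if t >= warmup:
                total += 1
                correct += int(res.method_id == bench.correct_method(region))
        return correct / total

    return play(local=True), play(local=False)
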