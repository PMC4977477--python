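"""Adaptive Neighbor Connection: bandit-driven selection of connection methods.

Each roadmap connection method (a distance metric + k-nearest-neighbor
selection + straight-line local planner bundle) is an arm of an Exp3-style
adversarial bandit.  The learner keeps one weight w_i per method and forms

    p*_i = (1 - gamma) * w_i / sum_j w_j + gamma / m            (exploration floor)
    x_i  = alpha + (1 - alpha) * (1 - (y - min_y)/(max_y - min_y))  (reward from
                                                                 edge weight y)
    x*_i = x_i / p*_i
    w_i <- w_i * exp(gamma * x*_i / m)                          (weight update)
    p_i  = (p*_i / c_i) / sum_j (p*_j / c_j)                    (cost adjustment)

where c_i is the average cost (potential-energy calls) of attempting a
connection with method i, and failed attempts earn reward 0 but still pay
their cost.  Unchosen methods receive reward 0 each step, so only the
chosen weight moves.

Two selection regimes share this machinery:

* **ANC-global** keeps a single persistent state fed by every attempt in
  the run.
* **ANC-local** keeps no persistent state: for each query it collects the
  ``nf_local`` nearest prior attempt records (torsional distance between
  the query and each record's node), replays them chronologically through
  a fresh state, and samples from the resulting cost-adjusted
  probabilities.  Reward normalization extrema are the running extrema over
  the replayed neighborhood, so learning is local in space as well as time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np

from .metrics import DistanceMetric, NeighborQuery, circular_difference, k_closest
from .local_planner import DEFAULT_RESOLUTION, connect_pair

__all__ = ["ConnectionMethod", "AttemptRecord", "AttemptOutcome", "BanditState",
           "History", "selection_probability_no_cost", "reward",
           "update_weights", "cost_adjusted_probability", "replay_history",
           "sample_method", "connect_node_local", "connect_node_global",
           "roadmap_attempt_executor", "ConnectResult"]

DEFAULT_GAMMA = 0.1
DEFAULT_ALPHA = 0.5
DEFAULT_NF_LOCAL = 40
DEFAULT_K = 20
UNSEEN_COST = 1.0  # optimistic average cost for methods with no history


@dataclass
class ConnectionMethod:
    """A (distance metric, k, local planner) bundle competing in the bandit."""

    id: str
    metric: Optional[DistanceMetric] = None
    k: int = DEFAULT_K
    resolution: float = DEFAULT_RESOLUTION

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class AttemptOutcome:
    """One local-planner attempt (query -> one neighbor)."""

    neighbor_id: str
    success: bool
    forward_weight: float
    reverse_weight: float
    cost: float


@dataclass(frozen=True)
class AttemptRecord:
    """History entry: who attempted what, with what reward and cost.

    The raw edge weight and success flag are kept alongside the recorded
    reward because localized replay re-normalizes rewards against
    neighborhood-local extrema.
    """

    node_id: str
    method_id: str
    reward: float
    cost: float
    step: int
    success: bool
    edge_weight: float
    node_torsions: Optional[np.ndarray] = None


class History:
    """Append-only attempt store with a strictly increasing step counter."""

    def __init__(self):
        self.records: List[AttemptRecord] = []
        self._step = 0

    def next_step(self) -> int:
        self._step += 1
        return self._step

    def append(self, rec: AttemptRecord) -> None:
        if self.records and rec.step <= self.records[-1].step:
            raise ValueError("record steps must be strictly increasing")
        self.records.append(rec)

    def __len__(self):
        return len(self.records)


@dataclass
class BanditState:
    """Weights, reward-normalization extrema and average costs for m arms."""

    method_ids: Sequence[str]
    gamma: float = DEFAULT_GAMMA
    alpha: float = DEFAULT_ALPHA
    weights: np.ndarray = None
    min_y: float = math.inf
    max_y: float = -math.inf
    cost_totals: np.ndarray = None
    cost_counts: np.ndarray = None

    def __post_init__(self):
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must be in [0, 1)")
        m = len(self.method_ids)
        if m < 1:
            raise ValueError("need at least one method")
        self.method_ids = tuple(self.method_ids)
        if self.weights is None:
            self.weights = np.ones(m)
        if self.cost_totals is None:
            self.cost_totals = np.zeros(m)
        if self.cost_counts is None:
            self.cost_counts = np.zeros(m)
        self._index = {mid: i for i, mid in enumerate(self.method_ids)}

    @property
    def m(self) -> int:
        return len(self.method_ids)

    def index(self, method_id: str) -> int:
        return self._index[method_id]

    def average_costs(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            avg = np.where(self.cost_counts > 0,
                           self.cost_totals / np.maximum(self.cost_counts, 1),
                           UNSEEN_COST)
        return np.maximum(avg, 1e-12)

    def observe(self, method_id: str, success: bool, edge_weight: float,
                cost: float) -> float:
        """Feed one attempt outcome through the full update; returns the
        reward credited to the chosen method."""
        if success and math.isfinite(edge_weight):
            self.min_y = min(self.min_y, edge_weight)
            self.max_y = max(self.max_y, edge_weight)
            x = reward(edge_weight, self)
        else:
            x = 0.0
        update_weights(self, method_id, x)
        i = self.index(method_id)
        self.cost_totals[i] += cost
        self.cost_counts[i] += 1
        return x


def selection_probability_no_cost(state: BanditState) -> np.ndarray:
    """p*_i = (1 - gamma) w_i / sum_j w_j + gamma / m."""
    w = state.weights
    return (1.0 - state.gamma) * w / w.sum() + state.gamma / state.m


def reward(edge_weight: float, state: BanditState) -> float:
    """Reward in [alpha, 1] from an edge weight, best-seen edge earning 1.

    A lone observation (min == max) earns 1 by convention.
    """
    lo, hi = state.min_y, state.max_y
    if not (math.isfinite(lo) and math.isfinite(hi)) or hi == lo:
        return 1.0
    frac = (edge_weight - lo) / (hi - lo)
    return state.alpha + (1.0 - state.alpha) * (1.0 - frac)


def update_weights(state: BanditState, method_id: str, x: float) -> BanditState:
    """Exponential weight update for the chosen method; zero-reward arms
    (including all unchosen ones) keep their weights."""
    if x < 0 or x > 1:
        raise ValueError("reward must lie in [0, 1]")
    if x == 0.0:
        return state
    i = state.index(method_id)
    p_star = selection_probability_no_cost(state)
    x_adj = x / p_star[i]
    state.weights[i] *= math.exp(state.gamma * x_adj / state.m)
    return state


def cost_adjusted_probability(state: BanditState) -> np.ndarray:
    """p_i proportional to p*_i / c_i, normalized to sum to 1."""
    p_star = selection_probability_no_cost(state)
    ratio = p_star / state.average_costs()
    return ratio / ratio.sum()


def sample_method(state: BanditState, methods: Sequence[ConnectionMethod],
                  rng: np.random.Generator) -> ConnectionMethod:
    """Inverse-CDF draw from the cost-adjusted probabilities, in the fixed
    method order (deterministic under a seeded generator)."""
    p = cost_adjusted_probability(state)
    u = rng.random()
    acc = 0.0
    for method, pi in zip(methods, p):
        acc += pi
        if u < acc:
            return method
    return methods[-1]


# ---------------------------------------------------------------------------
# Localized replay
# ---------------------------------------------------------------------------

def _torsional_rms(u: np.ndarray, v: np.ndarray) -> float:
    d = circular_difference(u, v)
    return float(np.sqrt(np.mean(d * d)))


def local_neighborhood(q_torsions: np.ndarray, history: History,
                       nf_local: int) -> list:
    """The nf_local prior attempt records nearest to the query (torsional
    distance to each record's node), in chronological order."""
    scored = []
    for rec in history.records:
        if rec.node_torsions is None:
            continue
        scored.append((_torsional_rms(q_torsions, rec.node_torsions),
                       rec.step, rec))
    scored.sort(key=lambda t: (t[0], t[1]))
    region = [rec for _, _, rec in scored[:nf_local]]
    region.sort(key=lambda r: r.step)
    return region


def replay_history(records: Sequence[AttemptRecord], method_ids: Sequence[str],
                   gamma: float = DEFAULT_GAMMA,
                   alpha: float = DEFAULT_ALPHA) -> BanditState:
    """Rebuild a fresh bandit state by replaying records chronologically.

    Rewards are recomputed from the raw edge weights against running
    extrema over the replayed records, so the same record set always
    produces the same state.
    """
    state = BanditState(method_ids=method_ids, gamma=gamma, alpha=alpha)
    for rec in records:
        state.observe(rec.method_id, rec.success, rec.edge_weight, rec.cost)
    return state


# ---------------------------------------------------------------------------
# Node connection drivers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConnectResult:
    method_id: str
    selection_probabilities: np.ndarray
    outcomes: tuple
    records: tuple  # the AttemptRecords appended to history


AttemptExecutor = Callable[[object, ConnectionMethod, np.random.Generator],
                           List[AttemptOutcome]]


def roadmap_attempt_executor(nodes_by_id: dict, topo, model) -> AttemptExecutor:
    """Standard executor: k-nearest neighbors under the method's metric,
    straight-line local planning against each."""

    def attempt(q, method: ConnectionMethod,
                rng: np.random.Generator) -> List[AttemptOutcome]:
        candidates = [c for c in nodes_by_id.values() if c.id != q.id]
        neighbors = k_closest(NeighborQuery(query=q, candidates=candidates,
                                            metric=method.metric, k=method.k))
        outcomes = []
        for nb in neighbors:
            res = connect_pair(q, nb, topo, model, method.resolution)
            outcomes.append(AttemptOutcome(
                neighbor_id=nb.id, success=res.success,
                forward_weight=res.forward_weight,
                reverse_weight=res.reverse_weight,
                cost=float(res.energy_calls)))
        return outcomes

    return attempt


def _record_outcomes(q, method: ConnectionMethod, outcomes, history: History,
                     reward_state: BanditState) -> tuple:
    """Append one AttemptRecord per local-planner attempt, crediting rewards
    against ``reward_state``'s running extrema."""
    records = []
    for out in outcomes:
        x = reward_state.observe(method.id, out.success, out.forward_weight,
                                 out.cost)
        rec = AttemptRecord(node_id=q.id, method_id=method.id, reward=x,
                            cost=out.cost, step=history.next_step(),
                            success=out.success, edge_weight=out.forward_weight,
                            node_torsions=np.asarray(q.torsions, dtype=float))
        history.append(rec)
        records.append(rec)
    return tuple(records)


def connect_node_local(q, methods: Sequence[ConnectionMethod], history: History,
                       rng: np.random.Generator, attempt: AttemptExecutor,
                       nf_local: int = DEFAULT_NF_LOCAL,
                       gamma: float = DEFAULT_GAMMA,
                       alpha: float = DEFAULT_ALPHA) -> ConnectResult:
    """ANC-local: replay the query's neighborhood history through a fresh
    bandit state, sample a method from the cost-adjusted probabilities, run
    its connection attempts, and log one record per attempt.

    With an empty history this reduces to a uniform (cold-start) draw.
    """
    method_ids = [mtd.id for mtd in methods]
    region = local_neighborhood(np.asarray(q.torsions, dtype=float),
                                history, nf_local)
    state = replay_history(region, method_ids, gamma, alpha)
    chosen = sample_method(state, methods, rng)
    probs = cost_adjusted_probability(state)
    outcomes = attempt(q, chosen, rng)
    records = _record_outcomes(q, chosen, outcomes, history, state)
    return ConnectResult(method_id=chosen.id, selection_probabilities=probs,
                         outcomes=tuple(outcomes), records=records)


def connect_node_global(q, methods: Sequence[ConnectionMethod],
                        state: BanditState, history: History,
                        rng: np.random.Generator,
                        attempt: AttemptExecutor) -> ConnectResult:
    """ANC-global: one persistent state shared across all nodes, no replay."""
    chosen = sample_method(state, methods, rng)
    probs = cost_adjusted_probability(state)
    outcomes = attempt(q, chosen, rng)
    records = _record_outcomes(q, chosen, outcomes, history, state)
    return ConnectResult(method_id=chosen.id, selection_probabilities=probs,
                         outcomes=tuple(outcomes), records=records)
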