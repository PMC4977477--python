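"""Straight-line local planner and energetic edge weighting.

A transition between two conformations is a straight-line interpolation of
all phi/psi torsions along the minimal angular path, discretized so no
torsion moves more than ``resolution`` degrees per step.  Each intermediate
is checked for feasibility (connecting-phase clash threshold); the edge
weight of a feasible transition is

    sum_i -log(P_i),   P_i = exp(-dE_i / kT) if dE_i > 0 else 1

over consecutive intermediates, so low weight means an energetically easy
(downhill-or-flat) transition and weights add along paths — shortest-weight
paths are maximum-probability paths.  Both traversal directions are scored:
dE is antisymmetric, so the forward and reverse weights differ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .energy import EnergyModel, total_energy
from .metrics import circular_difference
from .protein_model import Conformation, ProteinTopology, normalize_angle

__all__ = ["TransitionResult", "interpolate", "transition_probability",
           "connect_pair", "DEFAULT_RESOLUTION"]

DEFAULT_RESOLUTION = 5.0  # degrees, max per-torsion step


@dataclass(frozen=True)
class TransitionResult:
    success: bool
    forward_weight: float
    reverse_weight: float
    energy_calls: int
    intermediates: int


def interpolate(a: Conformation, b: Conformation, resolution: float = DEFAULT_RESOLUTION) -> list:
    """Uniform straight-line torsional path c_0 = a, ..., c_m = b.

    m = ceil(max per-torsion angular span / resolution), at least 1; every
    per-torsion step is <= resolution degrees along the minimal arc.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    span = circular_difference(b.torsions, a.torsions)
    m = max(1, int(math.ceil(np.abs(span).max() / resolution)))
    seq = [a]
    for j in range(1, m):
        t = normalize_angle(a.torsions + span * (j / m))
        seq.append(Conformation(torsions=t, id=f"{a.id}~{b.id}~{j}"))
    seq.append(b)
    return seq


def transition_probability(dE: float, kT: float) -> float:
    """Metropolis-style step probability: exp(-dE/kT) uphill, 1 otherwise."""
    if math.isinf(dE) and dE > 0:
        return 0.0
    if dE <= 0:
        return 1.0
    return math.exp(-dE / kT)


def connect_pair(a: Conformation, b: Conformation, topo: ProteinTopology,
                 model: EnergyModel,
                 resolution: float = DEFAULT_RESOLUTION) -> TransitionResult:
    """Attempt the straight-line transition a <-> b.

    Success requires every intermediate to be feasible at the connecting
    clash threshold.  ``energy_calls`` counts the fresh potential
    evaluations this attempt incurred (cached endpoint energies are free);
    failed attempts report infinite weights, never raise.
    """
    calls_before = model.call_counter
    seq = interpolate(a, b, resolution)
    energies = []
    feasible = True
    for c in seq:
        e = total_energy(topo, c, model, phase="connecting")
        energies.append(e)
        if not math.isfinite(e):
            feasible = False
            break  # no point evaluating past an infeasible intermediate
    calls = model.call_counter - calls_before
    if not feasible:
        return TransitionResult(success=False, forward_weight=math.inf,
                                reverse_weight=math.inf, energy_calls=calls,
                                intermediates=len(seq) - 2 if len(seq) > 2 else 0)
    fw = rv = 0.0
    for e0, e1 in zip(energies[:-1], energies[1:]):
        fw += -math.log(transition_probability(e1 - e0, model.kT))
        rv += -math.log(transition_probability(e0 - e1, model.kT))
    return TransitionResult(success=True, forward_weight=fw, reverse_weight=rv,
                            energy_calls=calls, intermediates=len(seq) - 2)
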