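"""Coarse-grained potential and feasibility checks.

The potential is a soft-constraint term over a Go-like constraint set plus a
hydrophobic contact term:

    U_tot = sum_constraints K_d * { [ (d_i - d_0)^2 + d_c^2 ]^(1/2) - d_c } + E_hp

with K_d = 100 kJ/mol and d_0 = d_c = 2 Angstrom.  Constraints are the
backbone covalent bonds plus native hydrogen bonds (carbonyl O to amide N
pairs within 3.5 A in the native structure, both residues inside a declared
secondary-structure segment).  E_hp is a step contact potential: every
hydrophobic residue pair (sequence separation >= 3) whose side-chain marker
atoms lie within a cutoff contributes a fixed (negative) energy.

A conformation is infeasible when any pair of atoms more than four covalent
bonds apart (and not partnered by a native hydrogen bond) comes closer than
a phase-dependent threshold (2.4 A while sampling, 1.0 A while connecting);
infeasible conformations score +inf so
downstream acceptance and transition probabilities degrade to zero instead
of raising.

Every fresh potential evaluation increments ``call_counter`` — this counter
is the cost currency of the bandit learner.  Cached energies are not
recounted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .protein_model import (
    CA_SLOT, CB_SLOT, C_SLOT, H_SLOT, N_SLOT, O_SLOT,
    Conformation, CoordinateSet, ProteinTopology, forward_kinematics,
)

__all__ = ["EnergyModel", "ConstraintSet", "build_constraints",
           "clash_check", "total_energy", "hydrophobic_term", "INFEASIBLE"]

INFEASIBLE = math.inf

HBOND_NATIVE_CUTOFF = 3.5  # Angstrom, O...N in the native structure
MIN_HBOND_SEPARATION = 2   # residues


@dataclass(frozen=True)
class ConstraintSet:
    """Atom-index pairs whose current lengths are the d_i of the potential."""

    pairs: tuple          # ((i, j), ...) atom indices into the 6n coordinate set
    roles: tuple          # "backbone" | "hbond", parallel to pairs
    native_lengths: np.ndarray  # Angstrom, parallel to pairs

    def __post_init__(self):
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate constraint pairs")
        if not (len(self.pairs) == len(self.roles) == len(self.native_lengths)):
            raise ValueError("constraint arrays must be parallel")

    def hbond_residue_pairs(self) -> list:
        """(residue_i, residue_j, native_length) for each hydrogen bond."""
        out = []
        for (a, b), role, d in zip(self.pairs, self.roles, self.native_lengths):
            if role == "hbond":
                out.append((a // 6, b // 6, float(d)))
        return out


def _covalent_bonds(n: int) -> list:
    bonds = []
    for i in range(n):
        base = 6 * i
        bonds += [(base + N_SLOT, base + H_SLOT),
                  (base + N_SLOT, base + CA_SLOT),
                  (base + CA_SLOT, base + CB_SLOT),
                  (base + CA_SLOT, base + C_SLOT),
                  (base + C_SLOT, base + O_SLOT)]
        if i + 1 < n:
            bonds.append((base + C_SLOT, 6 * (i + 1) + N_SLOT))
    return bonds


EXCLUSION_BOND_DEPTH = 4


def _exclusion_mask(n: int) -> np.ndarray:
    """Boolean (6n, 6n) mask, True for pairs exempt from clash checking:
    atoms within four covalent bonds of each other.  Pairs governed by a
    native hydrogen-bond constraint are exempted separately (the soft
    constraint term, not the hard threshold, controls their distance)."""
    n_atoms = 6 * n
    adj = [[] for _ in range(n_atoms)]
    for a, b in _covalent_bonds(n):
        adj[a].append(b)
        adj[b].append(a)
    mask = np.eye(n_atoms, dtype=bool)
    for src in range(n_atoms):
        dist = {src: 0}
        frontier = [src]
        for depth in range(1, EXCLUSION_BOND_DEPTH + 1):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = depth
                        nxt.append(v)
            frontier = nxt
        for v in dist:
            mask[src, v] = True
    return mask


@dataclass
class EnergyModel:
    """Potential parameters plus the monotone energy-call counter."""

    K_d: float = 100.0        # kJ/mol
    d_0: float = 2.0          # Angstrom
    d_c: float = 2.0          # Angstrom
    clash_sampling: float = 2.4   # Angstrom
    clash_connect: float = 1.0    # Angstrom
    hp_cutoff: float = 6.0        # Angstrom, side-chain marker contact
    hp_energy: float = -1.0       # kJ/mol per hydrophobic contact (<= 0)
    kT: float = 1.0               # reduced units
    call_counter: int = 0
    _topo_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.K_d <= 0 or self.d_c <= 0:
            raise ValueError("K_d and d_c must be positive")
        if self.clash_connect >= self.clash_sampling:
            raise ValueError("clash_connect must be below clash_sampling")
        if self.hp_energy > 0:
            raise ValueError("per-contact hydrophobic energy must be <= 0")

    def _derived(self, topo: ProteinTopology):
        key = id(topo)
        if key not in self._topo_cache:
            constraints = build_constraints(topo)
            mask = _exclusion_mask(topo.n)
            # Hydrogen-bonded amide pairs are held near contact by native
            # geometry (constraint term or helix capping), not by the hard
            # clash threshold: exempt O...N and O...H for every natively
            # close carbonyl/amide pair, segment-scoped or not.
            native = forward_kinematics(topo, topo.native_conformation()).coords
            for ri in range(topo.n):
                for rj in range(topo.n):
                    if abs(ri - rj) < MIN_HBOND_SEPARATION:
                        continue
                    o = 6 * ri + O_SLOT
                    nn, h = 6 * rj + N_SLOT, 6 * rj + H_SLOT
                    if np.linalg.norm(native[o] - native[nn]) <= HBOND_NATIVE_CUTOFF:
                        for a, b in ((o, nn), (o, h)):
                            mask[a, b] = mask[b, a] = True
            self._topo_cache[key] = {"exclusion": mask,
                                     "constraints": constraints}
        return self._topo_cache[key]

    def constraints(self, topo: ProteinTopology) -> ConstraintSet:
        return self._derived(topo)["constraints"]

    def exclusion_mask(self, topo: ProteinTopology) -> np.ndarray:
        return self._derived(topo)["exclusion"]


def build_constraints(topo: ProteinTopology) -> ConstraintSet:
    """Backbone covalent bonds plus native hydrogen bonds (O...N <= 3.5 A,
    sequence separation >= 2, both residues inside a native segment)."""
    native = forward_kinematics(topo, topo.native_conformation()).coords
    pairs = list(_covalent_bonds(topo.n))
    roles = ["backbone"] * len(pairs)

    in_segment = np.zeros(topo.n, dtype=bool)
    for seg in topo.native_segments:
        in_segment[seg.start:seg.end] = True

    O_idx = np.array([6 * i + O_SLOT for i in range(topo.n)])
    N_idx = np.array([6 * i + N_SLOT for i in range(topo.n)])
    d_ON = cdist(native[O_idx], native[N_idx])
    for i in range(topo.n):
        for j in range(topo.n):
            if abs(i - j) < MIN_HBOND_SEPARATION:
                continue
            if not (in_segment[i] and in_segment[j]):
                continue
            if d_ON[i, j] <= HBOND_NATIVE_CUTOFF:
                pairs.append((int(O_idx[i]), int(N_idx[j])))
                roles.append("hbond")

    arr = np.array(pairs)
    lengths = np.linalg.norm(native[arr[:, 0]] - native[arr[:, 1]], axis=1)
    return ConstraintSet(pairs=tuple(map(tuple, pairs)), roles=tuple(roles),
                         native_lengths=lengths)


def clash_check(topo: ProteinTopology, coords: CoordinateSet,
                model: EnergyModel, phase: str) -> bool:
    """True iff every non-exempt atom pair is at least the phase threshold
    apart (2.4 A sampling, 1.0 A connecting)."""
    if phase not in ("sampling", "connecting"):
        raise ValueError(f"unknown phase {phase!r}")
    threshold = model.clash_sampling if phase == "sampling" else model.clash_connect
    D = squareform(pdist(coords.coords))
    D[model.exclusion_mask(topo)] = np.inf
    return bool(D.min() >= threshold)


def hydrophobic_term(topo: ProteinTopology, coords: CoordinateSet,
                     hp_params: Optional[tuple] = None) -> float:
    """Step-function hydrophobic contact energy.

    hp_params = (cutoff A, per-contact kJ/mol); defaults (6.0, -1.0).
    Contacts are hydrophobic residue pairs with |i - j| >= 3 whose CB marker
    atoms are within the cutoff.
    """
    cutoff, per_contact = hp_params if hp_params is not None else (6.0, -1.0)
    hydro = np.flatnonzero(np.asarray(topo.hydrophobic))
    if hydro.size < 2:
        return 0.0
    cb = coords.coords[[6 * i + CB_SLOT for i in hydro]]
    D = squareform(pdist(cb))
    count = 0
    for a in range(hydro.size):
        for b in range(a + 1, hydro.size):
            if abs(int(hydro[a]) - int(hydro[b])) >= 3 and D[a, b] <= cutoff:
                count += 1
    return per_contact * count


def total_energy(topo: ProteinTopology, conf: Conformation, model: EnergyModel,
                 phase: str = "sampling",
                 coords: Optional[CoordinateSet] = None) -> float:
    """Potential energy in kJ/mol, +inf for infeasible conformations.

    Results are cached on the conformation; only fresh evaluations (cache
    misses) increment the model's call counter.
    """
    if conf.energy is not None:
        return conf.energy
    model.call_counter += 1
    if coords is None:
        coords = forward_kinematics(topo, conf)
    if not clash_check(topo, coords, model, phase):
        conf.energy = INFEASIBLE
        return INFEASIBLE
    cons = model.constraints(topo)
    arr = np.array(cons.pairs)
    d = np.linalg.norm(coords.coords[arr[:, 0]] - coords.coords[arr[:, 1]], axis=1)
    bracket = np.sqrt((d - model.d_0) ** 2 + model.d_c ** 2) - model.d_c
    e = model.K_d * float(bracket.sum())
    e += hydrophobic_term(topo, coords, (model.hp_cutoff, model.hp_energy))
    conf.energy = e
    return e
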