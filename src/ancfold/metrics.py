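"""Conformation distance metrics and exact neighbor selection.

Three metrics drive candidate-neighbor selection:

* ``euclidean`` — RMS difference over the 2n torsion angles, each difference
  taken as the minimal signed angular difference on the circle (359 deg and
  1 deg are 2 deg apart, not 358).
* ``cluster`` — the rigidity-map disagreement count (see :mod:`.rigidity`),
  with maps computed lazily and cached on the conformations.
* ``lrmsd`` — least RMSD over the 6n model atoms after optimal rigid-body
  superposition (Kabsch, via scipy's rotational alignment).

Neighbor search is exact brute force; ties are broken by conformation id so
results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .energy import EnergyModel
from .protein_model import (Conformation, CoordinateSet, ProteinTopology,
                            StructuralError, forward_kinematics)
from .rigidity import rigidity_distance, rigidity_map_of

__all__ = ["DistanceMetric", "NeighborQuery", "euclidean_distance", "rmsd",
           "lrmsd", "k_closest", "r_closest", "make_metric", "METRIC_NAMES"]

METRIC_NAMES = ("euclidean", "cluster", "lrmsd")


def circular_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal signed angular difference a - b on the circle, degrees."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return -(np.mod(-d + 180.0, 360.0) - 180.0)


def euclidean_distance(a: Conformation, b: Conformation) -> float:
    """RMS torsional difference: sqrt(sum(dphi^2 + dpsi^2) / 2n)."""
    if a.torsions.shape != b.torsions.shape:
        raise StructuralError("conformations have different torsion counts")
    d = circular_difference(a.torsions, b.torsions)
    return float(np.sqrt(np.mean(d * d)))


def rmsd(x: CoordinateSet, y: CoordinateSet) -> float:
    """Plain (non-superposed) RMSD over all 6n atoms, Angstrom."""
    if x.coords.shape != y.coords.shape:
        raise StructuralError("coordinate sets have different atom counts")
    diff = x.coords - y.coords
    return float(np.sqrt(np.sum(diff * diff) / x.n_atoms))


def lrmsd(x: CoordinateSet, y: CoordinateSet) -> float:
    """Least RMSD: minimum RMSD over all rigid-body superpositions."""
    if x.coords.shape != y.coords.shape:
        raise StructuralError("coordinate sets have different atom counts")
    xc = x.coords - x.coords.mean(axis=0)
    yc = y.coords - y.coords.mean(axis=0)
    if not (np.any(xc) and np.any(yc)):  # degenerate: all atoms coincident
        return float(np.sqrt(np.sum((xc - yc) ** 2) / x.n_atoms))
    rot, _ = Rotation.align_vectors(xc, yc)
    diff = xc - rot.apply(yc)
    return float(np.sqrt(np.sum(diff * diff) / x.n_atoms))


@dataclass
class DistanceMetric:
    """A named conformation-to-conformation distance."""

    name: str
    fn: Callable[[Conformation, Conformation], float]

    def __call__(self, a: Conformation, b: Conformation) -> float:
        return self.fn(a, b)


def make_metric(name: str, topo: Optional[ProteinTopology] = None,
                model: Optional[EnergyModel] = None) -> DistanceMetric:
    """Metric factory.  ``cluster`` and ``lrmsd`` need topology (and, for
    cluster, the energy model's constraint set); coordinates and rigidity
    maps are cached on the conformations."""
    if name == "euclidean":
        return DistanceMetric(name, euclidean_distance)
    if name == "lrmsd":
        if topo is None:
            raise ValueError("lrmsd metric requires a topology")
        cache: dict = {}

        def coords_of(c: Conformation) -> CoordinateSet:
            if c.id not in cache:
                cache[c.id] = forward_kinematics(topo, c)
            return cache[c.id]

        return DistanceMetric(name, lambda a, b: lrmsd(coords_of(a), coords_of(b)))
    if name == "cluster":
        if topo is None or model is None:
            raise ValueError("cluster metric requires topology and energy model")

        def dist(a: Conformation, b: Conformation) -> float:
            return float(rigidity_distance(rigidity_map_of(topo, a, model),
                                           rigidity_map_of(topo, b, model)))

        return DistanceMetric(name, dist)
    raise ValueError(f"unknown metric {name!r}; choose from {METRIC_NAMES}")


@dataclass
class NeighborQuery:
    query: Conformation
    candidates: Sequence[Conformation]
    metric: DistanceMetric
    k: Optional[int] = None
    r: Optional[float] = None

    def __post_init__(self):
        if (self.k is None) == (self.r is None):
            raise ValueError("specify exactly one of k or r")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")
        if self.r is not None and self.r < 0:
            raise ValueError("r must be >= 0")


def _scored(q: NeighborQuery) -> list:
    out = []
    for c in q.candidates:
        if c.id == q.query.id:
            continue  # the query never returns itself
        out.append((q.metric(q.query, c), c.id, c))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def k_closest(q: NeighborQuery) -> list:
    """The k nearest candidates, ascending by distance then id."""
    if q.k is None:
        raise ValueError("k_closest needs a k-query")
    return [c for _, _, c in _scored(q)[:q.k]]


def r_closest(q: NeighborQuery) -> list:
    """All candidates within radius r, ascending by distance then id."""
    if q.r is None:
        raise ValueError("r_closest needs an r-query")
    return [c for d, _, c in _scored(q) if d <= q.r]
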