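"""Rigid-cluster decomposition and the cluster-rigidity distance.

A rigidity map partitions the 2n torsion units (residue-major phi then psi)
into rigid clusters; two units are "marked" when they fall in the same
cluster.  The decomposition used here is a simplified rigid-cluster model:
clusters are the connected components of a graph whose edges join torsion
units coupled by a currently satisfied constraint —

* within each native secondary-structure segment the backbone units are
  chained together (the segment scaffold), and
* each native hydrogen bond whose current length is within 110 % of its
  native length couples the donor and acceptor residues' units.

The interface is partition-based so an exact pebble-game decomposition can
be dropped in later without touching any consumer.

The distance between two maps is the number of unordered unit pairs on
which the same-cluster indicators disagree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import EnergyModel, total_energy, forward_kinematics
from .protein_model import Conformation, ProteinTopology, StructuralError

__all__ = ["RigidityMap", "rigid_cluster_decomposition", "rigidity_distance",
           "rigidity_map_of"]

HBOND_SATISFIED_FACTOR = 1.10  # current length within 110 % of native


@dataclass(frozen=True)
class RigidityMap:
    """Partition of torsion units into rigid clusters.

    ``labels[u]`` is the cluster id of unit ``u``; the marked relation
    r(i, j) is ``labels[i] == labels[j]`` for i < j.
    """

    labels: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "labels",
                           np.asarray(self.labels, dtype=np.int64))

    @property
    def n_units(self) -> int:
        return self.labels.shape[0]

    def marked(self, i: int, j: int) -> bool:
        if i == j:
            raise ValueError("reflexive pairs are excluded from the map")
        return bool(self.labels[i] == self.labels[j])

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels)

    def is_rigid_unit(self, u: int) -> bool:
        """A unit is rigid when it shares its cluster with another unit."""
        return int(self.cluster_sizes()[self.labels[u]]) > 1


def rigid_cluster_decomposition(topo: ProteinTopology, conf: Conformation,
                                model: EnergyModel) -> RigidityMap:
    """Connected-component clustering of the satisfied-constraint graph."""
    n_units = topo.n_torsions
    parent = list(range(n_units))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    # Segment scaffolds: chain each segment's units together.
    for seg in topo.native_segments:
        units = range(2 * seg.start, 2 * seg.end)
        for u in units:
            if u + 1 < 2 * seg.end:
                union(u, u + 1)

    # Satisfied native hydrogen bonds couple the paired residues' units.
    hbonds = model.constraints(topo).hbond_residue_pairs()
    if hbonds:
        coords = forward_kinematics(topo, conf).coords
        cons = model.constraints(topo)
        for (a, b), role, d_native in zip(cons.pairs, cons.roles,
                                          cons.native_lengths):
            if role != "hbond":
                continue
            d = float(np.linalg.norm(coords[a] - coords[b]))
            if d <= HBOND_SATISFIED_FACTOR * d_native:
                ri, rj = a // 6, b // 6
                union(2 * ri, 2 * ri + 1)
                union(2 * rj, 2 * rj + 1)
                union(2 * ri, 2 * rj)

    roots = np.array([find(u) for u in range(n_units)])
    _, labels = np.unique(roots, return_inverse=True)
    return RigidityMap(labels=labels)


def rigidity_map_of(topo: ProteinTopology, conf: Conformation,
                    model: EnergyModel) -> RigidityMap:
    """Lazily computed, cached rigidity map of a conformation."""
    if conf.rigidity_map is None:
        conf.rigidity_map = rigid_cluster_decomposition(topo, conf, model)
    return conf.rigidity_map


def rigidity_distance(a_map: RigidityMap, b_map: RigidityMap) -> int:
    """Number of unordered unit pairs whose same-cluster status differs.

    Computed from the contingency table of the two partitions:
    |pairs same in a| + |pairs same in b| - 2 |pairs same in both|.
    """
    if a_map.n_units != b_map.n_units:
        raise StructuralError("rigidity maps have different unit domains")
    la, lb = a_map.labels, b_map.labels
    contingency = {}
    for x, y in zip(la, lb):
        contingency[(int(x), int(y))] = contingency.get((int(x), int(y)), 0) + 1

    def pairs(counts):
        return sum(c * (c - 1) // 2 for c in counts)

    same_a = pairs(np.bincount(la))
    same_b = pairs(np.bincount(lb))
    same_both = pairs(contingency.values())
    return int(same_a + same_b - 2 * same_both)
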