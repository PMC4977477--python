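"""Native-biased iterative conformational sampling.

Samples grow as a tree rooted at the native state: a parent is drawn
uniformly from the accepted set, a subset of its flexible torsions is
perturbed (rigidity-biased: torsion units outside rigid clusters are
weighted higher), and the proposal is retained by the energy-ramp
acceptance probability

    P(q) = 1                                if E(q) <  E_min
         = (E_max - E(q)) / (E_max - E_min) if E_min <  E(q) <= E_max
         = 0                                if E(q) >  E_max

where E_min is the energy of the open (fully extended) chain and
E_max = 2 E_min by default.  The boundary E(q) = E_min accepts with
probability 1 (continuity from below).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import EnergyModel, total_energy
from .protein_model import Conformation, ProteinTopology, perturb
from .rigidity import rigidity_map_of

__all__ = ["SamplerConfig", "SamplingError", "acceptance_probability",
           "open_chain_energy", "generate_samples"]

FLEXIBLE_WEIGHT = 4.0  # perturbation weight of flexible vs rigid units
RIGID_WEIGHT = 1.0


class SamplingError(RuntimeError):
    pass


@dataclass
class SamplerConfig:
    E_min: float                      # kJ/mol, energy of the open chain
    E_max: float = None               # kJ/mol, defaults to 2 * E_min
    target_count: int = 100
    max_attempts: int = 10000
    perturb_magnitude: float = 30.0   # degrees
    torsions_per_move: int = 4
    rng_seed: int = 0

    def __post_init__(self):
        if self.E_max is None:
            self.E_max = 2.0 * self.E_min
        if not self.E_max > self.E_min:
            raise ValueError("E_max must exceed E_min")
        if self.target_count < 1:
            raise ValueError("target_count must be >= 1")


def acceptance_probability(E_q: float, cfg: SamplerConfig) -> float:
    """Linear energy-ramp retention probability (see module docstring)."""
    if E_q <= cfg.E_min:
        return 1.0
    if E_q > cfg.E_max:
        return 0.0
    return (cfg.E_max - E_q) / (cfg.E_max - cfg.E_min)


def open_chain_energy(topo: ProteinTopology, model: EnergyModel) -> float:
    """Energy of the fully extended conformation (all flexible torsions 180)."""
    extended = Conformation(torsions=np.full(topo.n_torsions, 180.0),
                            id="open-chain")
    e = total_energy(topo, extended, model, phase="sampling")
    if not np.isfinite(e):
        raise SamplingError(
            "the extended chain clashes; choose a different E_min convention"
        )
    return e


def _perturbation_weights(topo: ProteinTopology, parent: Conformation,
                          model: EnergyModel) -> np.ndarray:
    """Per-flexible-torsion selection weights from the parent's rigidity map;
    flexible (singleton-cluster) units are favoured 4:1 over rigid ones."""
    rmap = rigidity_map_of(topo, parent, model)
    sizes = rmap.cluster_sizes()
    flex = topo.flexible_indices()
    w = np.where(sizes[rmap.labels[flex]] > 1, RIGID_WEIGHT, FLEXIBLE_WEIGHT)
    total = w.sum()
    if total <= 0:  # degenerate map: fall back to uniform
        return np.full(flex.size, 1.0 / flex.size)
    return w / total


def extend_samples(topo: ProteinTopology, model: EnergyModel,
                   cfg: SamplerConfig, accepted: list, count: int,
                   rng: np.random.Generator, start_index: int) -> list:
    """Append up to ``count`` newly accepted conformations to ``accepted``.

    Parents are drawn uniformly from the accepted set (breadth-biased tree
    growth); perturbation indices are drawn with rigidity-biased weights.
    Returns the new conformations.  Raises SamplingError when
    ``cfg.max_attempts`` is exhausted with nothing accepted.
    """
    flex = topo.flexible_indices()
    n_move = min(cfg.torsions_per_move, flex.size)
    new: list = []
    attempts = 0
    while len(new) < count and attempts < cfg.max_attempts:
        attempts += 1
        parent = accepted[rng.integers(len(accepted))]
        weights = _perturbation_weights(topo, parent, model)
        idx = rng.choice(flex, size=n_move, replace=False, p=weights)
        child = perturb(parent, idx, cfg.perturb_magnitude, rng,
                        new_id=f"s{start_index + len(new)}")
        e = total_energy(topo, child, model, phase="sampling")
        if rng.random() < acceptance_probability(e, cfg):
            accepted.append(child)
            new.append(child)
    if not new:
        raise SamplingError(
            f"no proposal accepted in {attempts} attempts; E window "
            f"[{cfg.E_min:.3g}, {cfg.E_max:.3g}] may be too tight"
        )
    return new


def generate_samples(topo: ProteinTopology, model: EnergyModel,
                     cfg: SamplerConfig, start_index: int = 0) -> list:
    """Generate up to ``cfg.target_count`` accepted conformations.

    The native state is always included (and counts toward the target).
    Sample ids are deterministic ("s<k>") so runs are byte-reproducible
    under a fixed seed.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    native = topo.native_conformation()
    total_energy(topo, native, model, phase="sampling")
    accepted = [native]
    if cfg.target_count > 1:
        extend_samples(topo, model, cfg, accepted, cfg.target_count - 1,
                       rng, start_index + 1)
    return accepted
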