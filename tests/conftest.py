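import numpy as np
import pytest

from ancfold.energy import EnergyModel
from ancfold.fixtures import ToySpec, make_toy_protein
from ancfold.protein_model import Conformation, ProteinTopology


@pytest.fixture(scope="session")
def helix_topo():
    """8-residue toy: one 5-residue helix plus a random (seeded) loop."""
    return make_toy_protein(ToySpec(n=8, segments=(("a1", "helix", 0, 5),),
                                    seed=3))


@pytest.fixture(scope="session")
def two_helix_topo():
    """14-residue toy with two helices separated by a loop (SSFO fixture)."""
    return make_toy_protein(
        ToySpec(n=14, segments=(("a1", "helix", 0, 6), ("a2", "helix", 8, 14)),
                seed=11))


@pytest.fixture()
def model():
    return EnergyModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_conformations(n_torsions, count, seed):
    """Seeded batch of random conformations with distinct ids."""
    gen = np.random.default_rng(seed)
    return [Conformation(torsions=gen.uniform(-180.0, 180.0, size=n_torsions),
                         id=f"r{i}")
            for i in range(count)]
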