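import numpy as np
import pytest

from implimem import MembraneGeometry, builtin_scale
from implimem.conformations import ConformationDB
from implimem.structures import default_atom_params, make_fixture


@pytest.fixture(scope="session")
def geom():
    return MembraneGeometry()


@pytest.fixture(scope="session")
def conf_db():
    return ConformationDB.ideal()


@pytest.fixture(scope="session")
def initial_params():
    return default_atom_params()


@pytest.fixture(scope="session")
def fp_scale():
    return builtin_scale()


@pytest.fixture(scope="session")
def hydrophobic_helix():
    return make_fixture("hydrophobic_helix", 18, seed=1)


@pytest.fixture(scope="session")
def amphipathic_helix():
    return make_fixture("amphipathic_helix", 18, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_bead_system(rng, n=50, spread=30.0):
    """Random one-bead system with positive areas and mixed transfer energies."""
    from implimem import Particle, ParticleSystem

    pos = rng.uniform(-spread, spread, size=(n, 3))
    parts = [
        Particle(
            id=i,
            position=pos[i],
            radius=2.0,
            sasa=float(rng.uniform(5.0, 80.0)),
            etr_per_area=float(rng.normal(0.0, 0.05)),
            residue_id=("A", "BEA", i + 1),
        )
        for i in range(n)
    ]
    return ParticleSystem(parts, "one-bead")
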