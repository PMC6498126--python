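import numpy as np
import pytest

from levelnet.molio import Dataset, LevelSet, Molecule
from levelnet.synthetic import SurrogateConfig, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset() -> Dataset:
    """100 synthetic labeled molecules, shared across tests (read-only)."""
    return generate_dataset(100, SurrogateConfig(), seed=11)


@pytest.fixture()
def water_like() -> Molecule:
    """A 3-atom bent molecule (O + 2 H), handy for tiny feature checks."""
    return Molecule(
        "w0",
        [8, 1, 1],
        [[0.0, 0.0, 0.0], [0.9572, 0.0, 0.0], [-0.2399, 0.9266, 0.0]],
    )


def random_molecule(rng, n_atoms=8, mol_id="rand", min_sep=0.7):
    """A random geometry with all pairs separated (rejection sampling)."""
    coords = np.empty((n_atoms, 3))
    placed = 0
    while placed < n_atoms:
        p = rng.uniform(0, 6.0, 3)
        if placed == 0 or np.linalg.norm(coords[:placed] - p, axis=1).min() >= min_sep:
            coords[placed] = p
            placed += 1
    zs = rng.choice([1, 6, 7, 8, 9], size=n_atoms)
    return Molecule(mol_id, zs, coords)


def rigid_motion(mol: Molecule, rng, mol_id=None) -> Molecule:
    """Apply a random rotation + translation to a molecule."""
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(random_state=np.random.RandomState(int(rng.integers(2**31))))
    coords = mol.coordinates @ rot.as_matrix().T + rng.uniform(-5, 5, 3)
    return Molecule(mol_id or mol.id, mol.atomic_numbers, coords)
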