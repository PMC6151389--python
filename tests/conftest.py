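import numpy as np
import pytest

from kinsel import (
    assign_atomic_properties,
    featurize_many,
    make_fixture_molecules,
)
from kinsel.molio import Molecule, Atom


@pytest.fixture(scope="session")
def fixture_molecules():
    """A dozen embeddable 3D structures shared across tests."""
    mols = make_fixture_molecules(12, seed=7)
    for m in mols:
        assign_atomic_properties(m)
    return mols


@pytest.fixture(scope="session")
def feature_matrix(fixture_molecules):
    return featurize_many(fixture_molecules)


HAND_SDF = """probe
  hand 3D

  2  1  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
M  END
$$$$
"""


@pytest.fixture
def hand_sdf_text():
    return HAND_SDF


def make_point_molecule(coords, props, elements=None):
    """Bare molecule with given coordinates and one preassigned property."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    elements = elements or ["C"] * n
    atoms = [
        Atom(element=e, coords=c, properties={"p": float(v), "identity": 1.0})
        for e, c, v in zip(elements, coords, props)
    ]
    # chain bonds keep the graph connected for topological descriptors
    bonds = [(i, i + 1, 1.0) for i in range(n - 1)]
    return Molecule(atoms=atoms, bonds=bonds, name="points", is_3d=True)


def rigid_transform(mol, rng):
    """Random rotation + translation applied to a copy of the molecule."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.normal(scale=10.0, size=3)
    atoms = [
        Atom(
            element=a.element,
            formal_charge=a.formal_charge,
            coords=a.coords @ q + t,
            n_implicit_h=a.n_implicit_h,
            properties=dict(a.properties),
        )
        for a in mol.atoms
    ]
    return Molecule(atoms=atoms, bonds=list(mol.bonds), name=mol.name, is_3d=True)


def permute_atoms(mol, perm):
    """Relabel atoms by the permutation `perm` (new index = position)."""
    inv = np.empty(len(perm), dtype=int)
    inv[perm] = np.arange(len(perm))
    atoms = [mol.atoms[p] for p in perm]
    atoms = [
        Atom(
            element=a.element,
            formal_charge=a.formal_charge,
            coords=None if a.coords is None else a.coords.copy(),
            n_implicit_h=a.n_implicit_h,
            properties=dict(a.properties),
        )
        for a in atoms
    ]
    bonds = [(int(inv[i]), int(inv[j]), o) for i, j, o in mol.bonds]
    return Molecule(atoms=atoms, bonds=bonds, name=mol.name, is_3d=mol.is_3d)
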