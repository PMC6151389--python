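"""Molecule parsing, representation, and per-atom property assignment.

Molecules are held in a light immutable-ish container (:class:`Molecule`) built
from RDKit parses of SDF (V2000) or SMILES input.  Descriptor code consumes the
heavy-atom graph by default, with implicit hydrogen counts folded into the
heavy atoms; explicit-hydrogen molecules are supported for property work that
needs them (e.g. inspecting hydrogen partial charges).

Per-atom properties (identity, electronegativity, polarizability, partial
charge) are assigned by :func:`assign_atomic_properties`.  The partial-charge
model is a sigma-framework iterative electronegativity equalization in the
PEOE family: fixed per-element electronegativities, charge transferred along
each bond proportional to the electronegativity difference, damped by (1/2)^k
over 6 iterations.  It is conformation independent, conserves total charge
exactly, and gives topologically equivalent atoms identical charges.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Atom",
    "Molecule",
    "MoleculeParseError",
    "UnknownElementError",
    "element_table",
    "parse_sdf",
    "parse_smiles",
    "write_sdf",
    "assign_atomic_properties",
]

# charge transferred per bond per iteration = (chi_j - chi_i) / CHI_NORM * (1/2)^k
CHI_NORM = 4.0
PEOE_ITERATIONS = 6


class MoleculeParseError(ValueError):
    """Raised when an SDF record or SMILES string cannot be parsed."""


class UnknownElementError(KeyError):
    """Raised when an element is missing from the shipped property table."""

    def __init__(self, element: str):
        super().__init__(element)
        self.element = element

    def __str__(self) -> str:  # pragma: no cover - message formatting
        return f"element {self.element!r} not in the shipped property table"


def element_table() -> dict[str, dict[str, float]]:
    """Shipped per-element reference values.

    Returns a map ``element -> {mass, electronegativity, polarizability,
    vdw_radius}`` (g/mol, Pauling units, A^3, A).
    """
    if not hasattr(element_table, "_cache"):
        table: dict[str, dict[str, float]] = {}
        text = (
            resources.files("kinsel.data")
            .joinpath("element_properties.csv")
            .read_text()
        )
        for row in csv.DictReader(text.splitlines()):
            table[row["element"]] = {
                k: float(v) for k, v in row.items() if k != "element"
            }
        element_table._cache = table  # type: ignore[attr-defined]
    return element_table._cache  # type: ignore[attr-defined]


@dataclass
class Atom:
    """One atom: element symbol, formal charge (e), optional coordinates (A),
    implicit hydrogen count, and assigned per-atom property values."""

    element: str
    formal_charge: int = 0
    coords: Optional[np.ndarray] = None
    n_implicit_h: int = 0
    properties: dict[str, float] = field(default_factory=dict)


@dataclass
class Molecule:
    """Ordered atoms plus a bond list ``(i, j, order)`` over atom indices."""

    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]
    name: str = ""
    is_3d: bool = False

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen = set()
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise MoleculeParseError(
                    f"molecule {self.name!r}: bond index ({i},{j}) out of range"
                )
            if i == j:
                raise MoleculeParseError(f"molecule {self.name!r}: self-bond at {i}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise MoleculeParseError(
                    f"molecule {self.name!r}: duplicate bond {key}"
                )
            seen.add(key)
        if self.is_3d and any(a.coords is None for a in self.atoms):
            raise MoleculeParseError(
                f"molecule {self.name!r}: flagged 3D but missing coordinates"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords_array(self) -> np.ndarray:
        if not self.is_3d:
            raise ValueError(
                f"molecule {self.name!r} has no 3D coordinates; supply an SDF "
                "with coordinates or embed the structure first"
            )
        return np.vstack([a.coords for a in self.atoms])

    def distance_matrix(self) -> np.ndarray:
        xyz = self.coords_array()
        d = xyz[:, None, :] - xyz[None, :, :]
        return np.sqrt((d * d).sum(axis=-1))

    def property_vector(self, name: str) -> np.ndarray:
        try:
            return np.array([a.properties[name] for a in self.atoms])
        except KeyError:
            raise KeyError(
                f"property {name!r} not assigned; call assign_atomic_properties first"
            ) from None

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_atoms, self.n_atoms), dtype=int)
        for i, j, _ in self.bonds:
            a[i, j] = a[j, i] = 1
        return a


def _from_rdkit(rdmol: Chem.Mol, name: str, keep_hs: bool,
                force_3d: bool = False) -> Molecule:
    if not keep_hs:
        rdmol = Chem.RemoveHs(rdmol)
    conf = rdmol.GetConformer() if rdmol.GetNumConformers() else None
    is_3d = bool(conf is not None and (conf.Is3D() or force_3d))
    atoms = []
    for a in rdmol.GetAtoms():
        coords = None
        if conf is not None:
            p = conf.GetAtomPosition(a.GetIdx())
            coords = np.array([p.x, p.y, p.z])
        atoms.append(
            Atom(
                element=a.GetSymbol(),
                formal_charge=a.GetFormalCharge(),
                coords=coords if is_3d else None,
                n_implicit_h=a.GetTotalNumHs(),
            )
        )
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
        for b in rdmol.GetBonds()
    ]
    return Molecule(atoms=atoms, bonds=bonds, name=name, is_3d=is_3d)


def parse_sdf(text: str, keep_hs: bool = False) -> list[Molecule]:
    """Parse a (possibly empty) concatenation of SDF V2000 records.

    Coordinates are read as Angstrom; a molecule is flagged 3D when its
    conformer has any nonzero z or the counts line declares 3D.  V3000 records
    are rejected.  Explicit hydrogens are folded into heavy-atom implicit-H
    counts unless ``keep_hs`` is set.
    """
    mols: list[Molecule] = []
    if not text.strip():
        return mols
    # split on record terminator to report the failing record index
    records = text.split("$$$$")
    blocks = [r for r in records if r.strip()]
    for idx, block in enumerate(blocks):
        block = block.lstrip("\n")
        if "V3000" in block:
            raise MoleculeParseError(
                f"SDF record {idx}: V3000 records are not supported (V2000 only)"
            )
        rdmol = Chem.MolFromMolBlock(block, removeHs=False, sanitize=True)
        if rdmol is None:
            # locate the offending line for the error message
            nline = len(block.splitlines())
            raise MoleculeParseError(
                f"SDF record {idx}: malformed V2000 block ({nline} lines)"
            )
        lines = block.splitlines()
        name = lines[0].strip() if lines else ""
        # the program/comment header may declare 3D outside the fixed column
        # RDKit reads; honor it either way
        header_3d = len(lines) > 1 and "3d" in lines[1].lower().split()
        mols.append(_from_rdkit(rdmol, name=name, keep_hs=keep_hs,
                                force_3d=header_3d))
    return mols


def parse_smiles(s: str, name: str = "", add_hs: bool = False) -> Molecule:
    """Parse a SMILES string into a connectivity-only (non-3D) Molecule.

    Implicit hydrogens are recorded per heavy atom; ``add_hs`` makes them
    explicit atoms instead (needed to inspect hydrogen partial charges).
    """
    rdmol = Chem.MolFromSmiles(s)
    if rdmol is None:
        raise MoleculeParseError(f"invalid SMILES: {s!r}")
    if add_hs:
        rdmol = Chem.AddHs(rdmol)
    return _from_rdkit(rdmol, name=name or s, keep_hs=add_hs)


def to_rdkit(mol: Molecule) -> Chem.Mol:
    """Rebuild an RDKit molecule (with conformer when 3D) from a Molecule."""
    rw = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.formal_charge)
        ra.SetNumExplicitHs(a.n_implicit_h)
        ra.SetNoImplicit(True)
        rw.AddAtom(ra)
    order_map = {
        1.0: Chem.BondType.SINGLE,
        1.5: Chem.BondType.AROMATIC,
        2.0: Chem.BondType.DOUBLE,
        3.0: Chem.BondType.TRIPLE,
    }
    for i, j, o in mol.bonds:
        rw.AddBond(i, j, order_map.get(o, Chem.BondType.SINGLE))
    m = rw.GetMol()
    Chem.SanitizeMol(m, catchErrors=True)
    if mol.is_3d:
        conf = Chem.Conformer(mol.n_atoms)
        for k, a in enumerate(mol.atoms):
            conf.SetAtomPosition(k, tuple(float(x) for x in a.coords))
        conf.Set3D(True)
        m.AddConformer(conf)
    m.SetProp("_Name", mol.name)
    return m


def write_sdf(mols: list[Molecule]) -> str:
    """Serialize molecules as concatenated V2000 records."""
    out = []
    for mol in mols:
        out.append(Chem.MolToMolBlock(to_rdkit(mol), kekulize=True))
        out.append("$$$$\n")
    return "".join(out)


def _check_elements(mol: Molecule) -> None:
    table = element_table()
    for a in mol.atoms:
        if a.element not in table:
            raise UnknownElementError(a.element)


def _peoe_charges(n: int, elements: list[str], formal: np.ndarray,
                  bonds: list[tuple[int, int, float]]) -> np.ndarray:
    """Damped electronegativity-equalization charges on an explicit graph."""
    table = element_table()
    chi = np.array([table[e]["electronegativity"] for e in elements])
    q = formal.astype(float).copy()
    for k in range(1, PEOE_ITERATIONS + 1):
        damp = 0.5**k
        dq = np.zeros(n)
        for i, j, _ in bonds:
            t = (chi[j] - chi[i]) / CHI_NORM * damp
            # charge flows from the less to the more electronegative atom
            dq[i] += t
            dq[j] -= t
        q += dq
    return q


def assign_atomic_properties(mol: Molecule, scheme: str = "default") -> Molecule:
    """Assign identity, electronegativity, polarizability, and partial charge.

    Partial charges are equalized over the full hydrogen-explicit sigma
    framework; charges of implicit hydrogens are folded back into their heavy
    atom, so the per-atom values on the heavy-atom graph remain a partition of
    the total charge.  The molecule is modified in place and returned.
    """
    if scheme != "default":
        raise ValueError(f"unknown property scheme {scheme!r}")
    _check_elements(mol)
    table = element_table()

    # build the H-explicit graph: each implicit H becomes a temporary node
    elements = [a.element for a in mol.atoms]
    formal = [a.formal_charge for a in mol.atoms]
    bonds = list(mol.bonds)
    parent = list(range(mol.n_atoms))
    for i, a in enumerate(mol.atoms):
        for _ in range(a.n_implicit_h):
            elements.append("H")
            formal.append(0)
            bonds.append((i, len(elements) - 1, 1.0))
            parent.append(i)

    q = _peoe_charges(len(elements), elements, np.array(formal, dtype=float), bonds)
    folded = np.zeros(mol.n_atoms)
    for node, p in enumerate(parent):
        folded[p] += q[node]

    for i, a in enumerate(mol.atoms):
        a.properties["identity"] = 1.0
        a.properties["electronegativity"] = table[a.element]["electronegativity"]
        a.properties["polarizability"] = table[a.element]["polarizability"]
        a.properties["partial_charge"] = folded[i]
    return mol
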