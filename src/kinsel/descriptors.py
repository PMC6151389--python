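"""Fixed-length invariant descriptor vectors for small molecules.

A molecule is encoded as the concatenation of descriptor *blocks* declared in
a :class:`DescriptorConfig`:

* ``scalar1d`` — formula-level scalars: molecular weight (implicit H
  included), total formal charge, heavy-atom count.
* ``scalar2d`` — connectivity-level scalars: H-bond donor and acceptor
  counts, ring count, additive surface-area and volume approximations.
* ``topo2da`` — topological autocorrelation: sums of property products over
  atom pairs binned by shortest bond-path length.
* ``rdf`` — radial distribution function: Gaussian-smoothed sums of property
  products over interatomic distances,
  ``RDF_k = sum_{i<j} p_i p_j exp(-B (k*dr - d_ij)^2)``.
* ``3da`` — 3D autocorrelation: the hard-binned analogue with half-open bins
  ``[k*d, (k+1)*d)``.

All blocks are sums over unordered atom pairs (or atoms), hence invariant to
atom reordering and — for the 3D blocks, which see only interatomic distances
— to rigid rotation and translation.  The shipped default layout totals
exactly 400 features: 8 scalars, 8 topological bins on identity, and for each
of four atomic properties (identity, partial charge, electronegativity,
polarizability) a 48-bin RDF (dr = 0.25 A, B = 100 A^-2) and a 48-bin 3DA
(d = 0.25 A), spanning distances up to 12 A.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .molio import Molecule, assign_atomic_properties, element_table

__all__ = [
    "BlockSpec",
    "DescriptorConfig",
    "FeatureVector",
    "default_config",
    "scalar_1d",
    "scalar_2d",
    "rdf",
    "three_da",
    "topo_2da",
    "featurize",
    "featurize_many",
]

SCALAR_1D_NAMES = ("molecular_weight", "total_charge", "heavy_atom_count")
SCALAR_2D_NAMES = ("hbd", "hba", "ring_count", "surface_area", "volume")


@dataclass(frozen=True)
class BlockSpec:
    """One descriptor block.

    kind: scalar1d | scalar2d | topo2da | rdf | 3da
    prop: atomic property aggregated (ignored for scalar blocks)
    n_bins: K, block length for binned kinds
    bin_width: dr in Angstrom (bond steps for topo2da are implicitly 1)
    smoothing: B in A^-2, rdf only
    """

    kind: str
    prop: str = "identity"
    n_bins: int = 1
    bin_width: float = 0.25
    smoothing: float = 100.0

    def __post_init__(self) -> None:
        if self.kind not in ("scalar1d", "scalar2d", "topo2da", "rdf", "3da"):
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.n_bins < 1 or self.bin_width <= 0 or self.smoothing <= 0:
            raise ValueError("block requires n_bins >= 1, bin_width > 0, smoothing > 0")

    @property
    def length(self) -> int:
        if self.kind == "scalar1d":
            return len(SCALAR_1D_NAMES)
        if self.kind == "scalar2d":
            return len(SCALAR_2D_NAMES)
        return self.n_bins

    def labels(self) -> list[str]:
        if self.kind == "scalar1d":
            return [f"scalar1d:{n}" for n in SCALAR_1D_NAMES]
        if self.kind == "scalar2d":
            return [f"scalar2d:{n}" for n in SCALAR_2D_NAMES]
        return [f"{self.kind}:{self.prop}:{k}" for k in range(self.n_bins)]


@dataclass(frozen=True)
class DescriptorConfig:
    blocks: tuple[BlockSpec, ...]

    @property
    def total_length(self) -> int:
        return sum(b.length for b in self.blocks)

    def labels(self) -> list[str]:
        out: list[str] = []
        for b in self.blocks:
            out.extend(b.labels())
        return out

    def needs_3d(self) -> bool:
        return any(b.kind in ("rdf", "3da") for b in self.blocks)

    def to_dict(self) -> dict:
        return {
            "blocks": [
                {
                    "kind": b.kind,
                    "prop": b.prop,
                    "n_bins": b.n_bins,
                    "bin_width": b.bin_width,
                    "smoothing": b.smoothing,
                }
                for b in self.blocks
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DescriptorConfig":
        return cls(blocks=tuple(BlockSpec(**b) for b in d["blocks"]))


def default_config() -> DescriptorConfig:
    """The shipped 400-feature layout."""
    blocks: list[BlockSpec] = [BlockSpec("scalar1d"), BlockSpec("scalar2d")]
    blocks.append(BlockSpec("topo2da", "identity", n_bins=8))
    for prop in ("identity", "partial_charge", "electronegativity", "polarizability"):
        blocks.append(BlockSpec("rdf", prop, n_bins=48, bin_width=0.25, smoothing=100.0))
    for prop in ("identity", "partial_charge", "electronegativity", "polarizability"):
        blocks.append(BlockSpec("3da", prop, n_bins=48, bin_width=0.25))
    cfg = DescriptorConfig(blocks=tuple(blocks))
    assert cfg.total_length == 400
    return cfg


@dataclass
class FeatureVector:
    values: np.ndarray
    layout: DescriptorConfig

    def __post_init__(self) -> None:
        if len(self.values) != self.layout.total_length:
            raise ValueError("feature vector length does not match layout")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")


def scalar_1d(mol: Molecule) -> dict[str, float]:
    """Formula-level scalars: MW (g/mol, implicit H included), total formal
    charge (e), heavy-atom count."""
    table = element_table()
    mw = 0.0
    heavy = 0
    for a in mol.atoms:
        if a.element not in table:
            from .molio import UnknownElementError

            raise UnknownElementError(a.element)
        mw += table[a.element]["mass"] + a.n_implicit_h * table["H"]["mass"]
        if a.element != "H":
            heavy += 1
    return {
        "molecular_weight": mw,
        "total_charge": float(sum(a.formal_charge for a in mol.atoms)),
        "heavy_atom_count": float(heavy),
    }


def scalar_2d(mol: Molecule) -> dict[str, float]:
    """Connectivity-level scalars.

    HBD: N/O atoms bearing at least one hydrogen.  HBA: N/O count.  Ring
    count: cyclomatic number (edges - vertices + components), which equals the
    SSSR size.  Surface area / volume: additive per-atom sphere increments
    from the shipped van der Waals radii (hydrogens folded into heavy atoms).
    """
    table = element_table()
    adj = mol.adjacency()
    h_neighbors = np.zeros(mol.n_atoms)
    for idx, a in enumerate(mol.atoms):
        h_neighbors[idx] += a.n_implicit_h
    for i, j, _ in mol.bonds:
        if mol.atoms[j].element == "H":
            h_neighbors[i] += 1
        if mol.atoms[i].element == "H":
            h_neighbors[j] += 1

    hbd = hba = 0
    area = vol = 0.0
    for idx, a in enumerate(mol.atoms):
        if a.element in ("N", "O"):
            hba += 1
            if h_neighbors[idx] >= 1:
                hbd += 1
        r = table[a.element]["vdw_radius"]
        area += 4.0 * np.pi * r * r
        vol += 4.0 / 3.0 * np.pi * r**3
        rh = table["H"]["vdw_radius"]
        area += a.n_implicit_h * 4.0 * np.pi * rh * rh
        vol += a.n_implicit_h * 4.0 / 3.0 * np.pi * rh**3

    n_components = _n_components(adj)
    ring_count = len(mol.bonds) - mol.n_atoms + n_components
    return {
        "hbd": float(hbd),
        "hba": float(hba),
        "ring_count": float(ring_count),
        "surface_area": area,
        "volume": vol,
    }


def _n_components(adj: np.ndarray) -> int:
    n = len(adj)
    seen = np.zeros(n, dtype=bool)
    comps = 0
    for s in range(n):
        if seen[s]:
            continue
        comps += 1
        stack = [s]
        seen[s] = True
        while stack:
            u = stack.pop()
            for v in np.nonzero(adj[u])[0]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
    return comps


def _pair_products(mol: Molecule, prop: str):
    p = mol.property_vector(prop)
    d = mol.distance_matrix()
    iu, ju = np.triu_indices(mol.n_atoms, k=1)
    return p[iu] * p[ju], d[iu, ju]


def rdf(mol: Molecule, prop: str, n_bins: int, bin_width: float,
        smoothing: float) -> np.ndarray:
    """Gaussian-smoothed radial distribution of property products.

    ``RDF_k = sum_{i<j} p_i p_j exp(-B (r_k - d_ij)^2)`` with
    ``r_k = k * bin_width``, k = 0..K-1.  Self-pairs are excluded.
    """
    if mol.n_atoms < 2:
        return np.zeros(n_bins)
    pp, dist = _pair_products(mol, prop)
    r = np.arange(n_bins) * bin_width
    g = np.exp(-smoothing * (r[:, None] - dist[None, :]) ** 2)
    return g @ pp


def three_da(mol: Molecule, prop: str, n_bins: int, bin_width: float) -> np.ndarray:
    """Hard-binned 3D autocorrelation with half-open bins [k*d, (k+1)*d);
    pairs beyond the grid are dropped."""
    if mol.n_atoms < 2:
        return np.zeros(n_bins)
    pp, dist = _pair_products(mol, prop)
    bins = np.floor(dist / bin_width).astype(int)
    keep = bins < n_bins
    out = np.zeros(n_bins)
    np.add.at(out, bins[keep], pp[keep])
    return out


def topo_2da(mol: Molecule, prop: str, n_bins: int) -> np.ndarray:
    """Topological autocorrelation over shortest bond-path distances.

    Bin 0 holds ``sum_i p_i^2``; bin k holds the sum of ``p_i p_j`` over pairs
    at graph distance k.  Disconnected inputs are handled per component (pairs
    across components are unreachable and simply never counted).
    """
    p = mol.property_vector(prop)
    out = np.zeros(n_bins)
    out[0] = float(np.sum(p * p))
    if mol.n_atoms > 1 and mol.bonds:
        rows = [i for i, j, _ in mol.bonds] + [j for i, j, _ in mol.bonds]
        cols = [j for i, j, _ in mol.bonds] + [i for i, j, _ in mol.bonds]
        g = csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(mol.n_atoms, mol.n_atoms)
        )
        d = shortest_path(g, method="D", unweighted=True)
        iu, ju = np.triu_indices(mol.n_atoms, k=1)
        pd = d[iu, ju]
        finite = np.isfinite(pd)
        bins = pd[finite].astype(int)
        keep = bins < n_bins
        np.add.at(out, bins[keep], (p[iu] * p[ju])[finite][keep])
    return out


def _needs_properties(cfg: DescriptorConfig) -> bool:
    return any(b.kind in ("rdf", "3da", "topo2da") for b in cfg.blocks)


def featurize(mol: Molecule, config: Optional[DescriptorConfig] = None) -> FeatureVector:
    """Concatenate all configured blocks into one deterministic vector."""
    cfg = config or default_config()
    if _needs_properties(cfg) and (
        not mol.atoms or "identity" not in mol.atoms[0].properties
    ):
        assign_atomic_properties(mol)
    parts: list[np.ndarray] = []
    for b in cfg.blocks:
        try:
            if b.kind == "scalar1d":
                s = scalar_1d(mol)
                parts.append(np.array([s[n] for n in SCALAR_1D_NAMES]))
            elif b.kind == "scalar2d":
                s = scalar_2d(mol)
                parts.append(np.array([s[n] for n in SCALAR_2D_NAMES]))
            elif b.kind == "topo2da":
                parts.append(topo_2da(mol, b.prop, b.n_bins))
            elif b.kind == "rdf":
                parts.append(rdf(mol, b.prop, b.n_bins, b.bin_width, b.smoothing))
            elif b.kind == "3da":
                parts.append(three_da(mol, b.prop, b.n_bins, b.bin_width))
        except Exception as e:
            raise type(e)(
                f"descriptor block {b.kind}:{b.prop} failed for "
                f"molecule {mol.name!r}: {e}"
            ) from e
    return FeatureVector(values=np.concatenate(parts), layout=cfg)


def featurize_many(
    mols: list[Molecule], config: Optional[DescriptorConfig] = None
) -> np.ndarray:
    """Feature matrix, one row per molecule."""
    cfg = config or default_config()
    return np.vstack([featurize(m, cfg).values for m in mols])
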