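"""Synthetic fixtures: 3D molecule sets and planted-signal Kd panels.

Real panel data of the kind this package models (a few dozen inhibitors
profiled against hundreds of kinases) cannot ship with the code, so every
pipeline stage is exercised against synthetic stand-ins:

* :func:`make_fixture_molecules` builds small drug-like organic structures —
  alkanes, aromatics, and H-bonding heteroatom variants, plus seeded
  substituent-decorated derivatives — embedded in 3D with RDKit's distance
  geometry (ETKDG), so the full descriptor stack applies.
* :func:`make_planted_kd_matrix` plants a known structure-activity signal: for
  each *signal* kinase the log10 Kd (uM) is an affine function of the
  standardized mean of a secret subset of descriptor features plus Gaussian
  noise; the intercept is calibrated so the active fraction at the 10 uM
  cutoff hits a prevalence target.  *Noise* kinases draw log-Kd independent of
  structure.  The ground truth is returned so tests can check that training
  recovers the planted signal (high AUC on signal kinases, chance on noise
  kinases).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .dataset import ActivityMatrix
from .descriptors import DescriptorConfig, default_config, featurize_many
from .molio import Molecule, _from_rdkit

__all__ = ["PlantedPanelSpec", "make_fixture_molecules", "make_planted_kd_matrix"]

# curated base structures: alkanes/alicyclics, aromatics, H-bond donors and
# acceptors, halides — small enough to embed instantly, diverse in descriptor
# space
BASE_SMILES = [
    "CC", "CCC", "CCCC", "CC(C)C", "CCCCC", "C1CCCCC1", "C1CCCC1",
    "c1ccccc1", "Cc1ccccc1", "c1ccc2ccccc2c1", "c1ccncc1", "c1ccoc1",
    "c1cc[nH]c1", "c1ccsc1",
    "CO", "CCO", "CC(C)O", "OCCO", "CC(=O)O", "CC(=O)OC", "CC(=O)N",
    "CCN", "CCNC", "CN(C)C", "NCCO", "NC(=O)c1ccccc1", "Oc1ccccc1",
    "Nc1ccccc1", "COc1ccccc1", "CC#N", "CCl", "ClCCCl", "FC(F)F",
    "BrCC", "CSC", "CS(=O)C", "O=S(=O)(N)c1ccccc1",
]

# one-point substituents appended to a scaffold carbon to make decorated
# variants (SMILES fragments valid as suffixes of "...C")
SUBSTITUENTS = ["C", "CC", "O", "N", "F", "Cl", "C(=O)O", "C#N", "OC", "C(C)C"]
SCAFFOLDS = ["c1ccccc1", "C1CCCCC1", "c1ccncc1", "CCCC", "c1ccoc1"]


def _embed(smiles: str, name: str, seed: int) -> Molecule | None:
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        return None
    rdmol = Chem.AddHs(rdmol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed % (2**31 - 1)
    if AllChem.EmbedMolecule(rdmol, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(rdmol, params) != 0:
            return None
    AllChem.MMFFOptimizeMolecule(rdmol, maxIters=200)
    return _from_rdkit(rdmol, name=name, keep_hs=False)


def make_fixture_molecules(n: int, seed: int) -> list[Molecule]:
    """Build `n` valid 3D molecules, deterministically from `seed`.

    The curated base set comes first; further structures are seeded decorated
    variants (scaffold plus 1-3 substituents).  Every returned molecule has
    3D coordinates and featurizes under the default layout.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    mols: list[Molecule] = []
    for i, smi in enumerate(BASE_SMILES[:n]):
        m = _embed(smi, name=f"base_{i}_{smi}", seed=seed + i)
        if m is not None:
            mols.append(m)
    attempt = 0
    while len(mols) < n and attempt < 50 * n:
        attempt += 1
        scaffold = SCAFFOLDS[int(rng.integers(len(SCAFFOLDS)))]
        k = int(rng.integers(1, 4))
        subs = [SUBSTITUENTS[int(rng.integers(len(SUBSTITUENTS)))] for _ in range(k)]
        # each substituent extends a side chain off the scaffold
        smi = scaffold + "".join("C" + s for s in subs)
        m = _embed(smi, name=f"variant_{attempt}_{smi}",
                   seed=seed + 1000 + attempt)
        if m is not None:
            mols.append(m)
    if len(mols) < n:
        raise RuntimeError("could not generate enough embeddable structures")
    return mols[:n]


@dataclass
class PlantedPanelSpec:
    """Conditions of a planted-signal compound x kinase panel.

    beta is the effect size on standardized descriptor signal (log10-Kd units
    per SD); sigma the log10-Kd noise SD; prevalence the target active
    fraction at the 10 uM cutoff.
    """

    n_kinases: int = 20
    n_signal_kinases: int = 5
    n_signal_features: int = 5
    beta: float = 2.0
    sigma: float = 0.3
    prevalence: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signal_kinases > self.n_kinases:
            raise ValueError("more signal kinases than kinases")
        if self.sigma < 0 or self.beta < 0:
            raise ValueError("beta and sigma must be non-negative")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")


KD_FLOOR_UM = 1e-4
CALIBRATION_CUTOFF_UM = 10.0


def _calibrated_intercept(v: np.ndarray, prevalence: float) -> float:
    """Intercept a so that #{a + v_i < log10(cutoff)} / n ~= prevalence.

    Chooses a midpoint between order statistics of -v, giving the closest
    achievable active count.
    """
    n = len(v)
    target = int(round(prevalence * n))
    if target < 1 or target >= n:
        raise ValueError("prevalence target unachievable at this sample size")
    # actives are the smallest a+v; sort ascending
    s = np.sort(v)
    lo, hi = s[target - 1], s[target]
    if lo == hi:
        raise ValueError("tied log-Kd values prevent exact calibration")
    c = np.log10(CALIBRATION_CUTOFF_UM)
    return c - (lo + hi) / 2.0


def make_planted_kd_matrix(
    mols: list[Molecule],
    spec: PlantedPanelSpec,
    config: DescriptorConfig | None = None,
) -> tuple[ActivityMatrix, dict]:
    """Generate the panel and its ground truth.

    For signal kinase k:  log10 Kd_i = a_k - beta * z_i + eps_i, where z_i is
    the standardized mean of that kinase's signal features for compound i and
    eps ~ N(0, sigma).  Noise kinases draw log10 Kd ~ a_k + eps with the same
    calibrated prevalence.  Kd is floored at 1e-4 uM.
    """
    cfg = config or default_config()
    X = featurize_many(mols, cfg)
    rng = np.random.default_rng(spec.seed)

    # features informative enough to plant signal in: nonzero variance
    variable = np.nonzero(X.std(axis=0) > 1e-9)[0]
    if variable.size < spec.n_signal_features:
        raise ValueError("not enough variable features to plant a signal")
    Xz = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1, X.std(axis=0))

    n = len(mols)
    kd = np.empty((n, spec.n_kinases))
    truth: dict = {"signal_kinases": [], "signal_features": {}, "intercepts": {},
                   "spec": {"beta": spec.beta, "sigma": spec.sigma,
                            "prevalence": spec.prevalence, "seed": spec.seed}}
    signal_ids = list(range(spec.n_signal_kinases))
    for k in range(spec.n_kinases):
        kin = f"kinase_{k:03d}"
        eps = rng.normal(0.0, spec.sigma, size=n)
        if k in signal_ids:
            feats = rng.choice(variable, size=spec.n_signal_features, replace=False)
            z = Xz[:, feats].mean(axis=1)
            zsd = z.std()
            if zsd > 0:
                z = (z - z.mean()) / zsd
            v = -spec.beta * z + eps
            truth["signal_kinases"].append(kin)
            truth["signal_features"][kin] = [int(f) for f in feats]
        else:
            v = eps
        a = _calibrated_intercept(v, spec.prevalence)
        truth["intercepts"][kin] = float(a)
        kd[:, k] = np.maximum(10.0 ** (a + v), KD_FLOOR_UM)

    m = ActivityMatrix(
        compounds=[mol.name for mol in mols],
        kinases=[f"kinase_{k:03d}" for k in range(spec.n_kinases)],
        kd=kd,
    )
    return m, truth
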