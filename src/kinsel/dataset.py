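"""Activity panels: Kd matrices, binarization at cutoffs, normalization, folds.

The panel is a compound x kinase matrix of equilibrium dissociation constants
(Kd, micromolar).  Cells may be missing: panel assays of this kind report
binders only, so a missing cell is treated as inactive at every cutoff.  A
compound is *active* against a kinase at cutoff c when Kd < c (strict).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "ActivityMatrix",
    "LabelMatrix",
    "Normalizer",
    "DEFAULT_CUTOFFS_UM",
    "load_activity_csv",
    "binarize",
    "fit_normalizer",
    "split_folds",
]

DEFAULT_CUTOFFS_UM = (0.1, 0.5, 1.0, 3.0, 10.0)


@dataclass
class ActivityMatrix:
    """Compound x kinase Kd values in uM; NaN marks a missing measurement."""

    compounds: list[str]
    kinases: list[str]
    kd: np.ndarray  # shape (n_compounds, n_kinases), uM, NaN = missing

    def __post_init__(self) -> None:
        self.kd = np.asarray(self.kd, dtype=float)
        if self.kd.shape != (len(self.compounds), len(self.kinases)):
            raise ValueError("kd shape does not match id lists")
        if np.any(self.kd[~np.isnan(self.kd)] < 0):
            raise ValueError("negative Kd values are not physical")
        for name, ids in (("compound", self.compounds), ("kinase", self.kinases)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.kd, index=self.compounds, columns=self.kinases)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index_label="compound_id")


@dataclass
class LabelMatrix:
    """Binary activity view of an ActivityMatrix at one Kd cutoff."""

    compounds: list[str]
    kinases: list[str]
    labels: np.ndarray  # {0,1}, same shape as the source kd matrix
    cutoff_uM: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.labels, index=self.compounds, columns=self.kinases)


def load_activity_csv(path_or_buf: Union[str, Path, io.StringIO]) -> ActivityMatrix:
    """Read a compound x kinase Kd CSV.

    Rows are compounds (first column holds ids), columns kinases, blank cells
    missing.  Units are uM unless the id header cell mentions ``nM``, in which
    case values are divided by 1000.
    """
    df = pd.read_csv(path_or_buf, index_col=0)
    scale = 1.0
    if df.index.name and "nm" in str(df.index.name).lower().replace("_", " "):
        scale = 1e-3
    kd = df.to_numpy(dtype=float) * scale
    return ActivityMatrix(
        compounds=[str(c) for c in df.index],
        kinases=[str(k) for k in df.columns],
        kd=kd,
    )


def binarize(m: ActivityMatrix, cutoff_uM: float) -> LabelMatrix:
    """Label 1 iff Kd is present and strictly below the cutoff."""
    if cutoff_uM <= 0:
        raise ValueError("cutoff must be positive")
    labels = np.where(np.isnan(m.kd), 0, (m.kd < cutoff_uM).astype(int))
    return LabelMatrix(
        compounds=list(m.compounds),
        kinases=list(m.kinases),
        labels=labels,
        cutoff_uM=cutoff_uM,
    )


@dataclass
class Normalizer:
    """Per-feature z-scoring statistics learned from training rows.

    Constant columns (sd = 0) are flagged and mapped to 0 on transform; the
    inverse maps them back to their mean.
    """

    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.constant is None:
            self.constant = self.sd == 0

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        sd = np.where(self.constant, 1.0, self.sd)
        out = (X - self.mean) / sd
        out[:, self.constant] = 0.0
        return out

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        sd = np.where(self.constant, 0.0, self.sd)
        return Z * sd + self.mean

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "constant": self.constant.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        return cls(
            mean=np.array(d["mean"]),
            sd=np.array(d["sd"]),
            constant=np.array(d["constant"], dtype=bool),
        )


def fit_normalizer(X: np.ndarray) -> Normalizer:
    """Learn per-column mean/sd from at least two training rows."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("normalizer needs a 2D matrix with >= 2 rows")
    return Normalizer(mean=X.mean(axis=0), sd=X.std(axis=0, ddof=0))


def split_folds(n_compounds: int, k: int, seed: int) -> np.ndarray:
    """Seeded compound-level k-fold assignment; fold sizes differ by <= 1."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n_compounds:
        raise ValueError("more folds than compounds")
    rng = np.random.default_rng(seed)
    assignment = np.arange(n_compounds) % k
    rng.shuffle(assignment)
    return assignment
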