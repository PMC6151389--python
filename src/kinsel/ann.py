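"""Multi-task feed-forward network for panel activity prediction.

One hidden layer of sigmoid units maps the 400 descriptor inputs to one
sigmoid output per kinase (default 400 -> 32 -> N).  Training is classic
online back-propagation on a sum-of-squares loss with momentum:

    dw(t) = -eta * dE/dw + alpha * dw(t-1),   E = 1/2 sum_o (y_o - t_o)^2

applied after every presented example, with a seeded shuffle of the
presentation order each epoch.  Defaults eta = 0.1, alpha = 0.5.  A
cross-entropy loss is available behind the config switch; with sigmoid
outputs it only changes the output delta from (y-t)*y*(1-y) to (y-t).

Optional monitoring data enables early stopping: training halts when the
monitoring loss has not improved for `patience` consecutive epochs and the
best-seen weights are restored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .dataset import Normalizer
from .descriptors import DescriptorConfig, default_config, featurize
from .molio import Molecule

__all__ = ["TrainingConfig", "AnnModel", "init_model", "forward", "backprop_step",
           "train", "predict_profile", "save_model", "load_model"]


def _sigmoid(t: np.ndarray) -> np.ndarray:
    # clip keeps exp in range; saturation below 1e-217 is indistinguishable
    return 1.0 / (1.0 + np.exp(-np.clip(t, -500.0, 500.0)))


@dataclass
class TrainingConfig:
    eta: float = 0.1
    alpha: float = 0.5
    epochs: int = 500
    shuffle_seed: int = 0
    loss: str = "sse"  # "sse" or "cross_entropy"
    patience: int = 50  # early-stop patience on monitoring loss, if monitor given

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must be in [0, 1)")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.loss not in ("sse", "cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class AnnModel:
    W1: np.ndarray  # hidden x input
    b1: np.ndarray  # hidden
    W2: np.ndarray  # output x hidden
    b2: np.ndarray  # output
    normalizer: Optional[Normalizer] = None
    kinase_ids: Optional[list[str]] = None
    seed: int = 0
    training_config: Optional[TrainingConfig] = None
    # momentum state (previous updates), carried between backprop steps
    _vW1: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _vb1: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _vW2: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _vb2: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        h, i = self.W1.shape
        o = self.W2.shape[0]
        if self.W2.shape[1] != h or len(self.b1) != h or len(self.b2) != o:
            raise ValueError("inconsistent weight shapes")
        for name in ("_vW1", "_vb1", "_vW2", "_vb2"):
            if getattr(self, name) is None:
                ref = getattr(self, name[2:])
                setattr(self, name, np.zeros_like(ref))

    @property
    def n_in(self) -> int:
        return self.W1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    @property
    def n_out(self) -> int:
        return self.W2.shape[0]

    def copy(self) -> "AnnModel":
        return AnnModel(
            W1=self.W1.copy(), b1=self.b1.copy(),
            W2=self.W2.copy(), b2=self.b2.copy(),
            normalizer=self.normalizer, kinase_ids=self.kinase_ids,
            seed=self.seed, training_config=self.training_config,
            _vW1=self._vW1.copy(), _vb1=self._vb1.copy(),
            _vW2=self._vW2.copy(), _vb2=self._vb2.copy(),
        )


def init_model(n_in: int, n_hidden: int, n_out: int, seed: int,
               kinase_ids: Optional[list[str]] = None) -> AnnModel:
    """Seeded uniform initialization in [-1/sqrt(fan_in), +1/sqrt(fan_in)];
    biases zero."""
    if min(n_in, n_hidden, n_out) < 1:
        raise ValueError("all layer sizes must be >= 1")
    rng = np.random.default_rng(seed)
    s1 = 1.0 / np.sqrt(n_in)
    s2 = 1.0 / np.sqrt(n_hidden)
    return AnnModel(
        W1=rng.uniform(-s1, s1, size=(n_hidden, n_in)),
        b1=np.zeros(n_hidden),
        W2=rng.uniform(-s2, s2, size=(n_out, n_hidden)),
        b2=np.zeros(n_out),
        kinase_ids=kinase_ids,
        seed=seed,
    )


def forward(model: AnnModel, x: np.ndarray) -> np.ndarray:
    """Sigmoid-sigmoid forward pass; outputs strictly in (0, 1)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.n_in:
        raise ValueError(f"input length {x.shape[-1]} != model n_in {model.n_in}")
    h = _sigmoid(x @ model.W1.T + model.b1)
    return _sigmoid(h @ model.W2.T + model.b2)


def _gradients(model: AnnModel, x: np.ndarray, target: np.ndarray, loss: str):
    h = _sigmoid(model.W1 @ x + model.b1)
    y = _sigmoid(model.W2 @ h + model.b2)
    if loss == "sse":
        delta_o = (y - target) * y * (1.0 - y)
    else:  # cross_entropy with sigmoid outputs
        delta_o = y - target
    delta_h = (model.W2.T @ delta_o) * h * (1.0 - h)
    return (
        np.outer(delta_o, h), delta_o,  # dE/dW2, dE/db2
        np.outer(delta_h, x), delta_h,  # dE/dW1, dE/db1
        y,
    )


def backprop_step(model: AnnModel, x: np.ndarray, target: np.ndarray,
                  config: TrainingConfig) -> AnnModel:
    """One online update (in place) with momentum; returns the model."""
    x = np.asarray(x, dtype=float)
    target = np.asarray(target, dtype=float)
    if x.shape != (model.n_in,) or target.shape != (model.n_out,):
        raise ValueError("x/target shape mismatch")
    gW2, gb2, gW1, gb1, _ = _gradients(model, x, target, config.loss)
    model._vW2 = -config.eta * gW2 + config.alpha * model._vW2
    model._vb2 = -config.eta * gb2 + config.alpha * model._vb2
    model._vW1 = -config.eta * gW1 + config.alpha * model._vW1
    model._vb1 = -config.eta * gb1 + config.alpha * model._vb1
    model.W2 += model._vW2
    model.b2 += model._vb2
    model.W1 += model._vW1
    model.b1 += model._vb1
    return model


def _loss(model: AnnModel, X: np.ndarray, Y: np.ndarray, loss: str) -> float:
    y = forward(model, X)
    if loss == "sse":
        return float(0.5 * np.sum((y - Y) ** 2) / len(X))
    eps = 1e-12
    return float(-np.sum(Y * np.log(y + eps) + (1 - Y) * np.log(1 - y + eps)) / len(X))


def train(model: AnnModel, X: np.ndarray, Y: np.ndarray, config: TrainingConfig,
          monitor: Optional[tuple[np.ndarray, np.ndarray]] = None
          ) -> tuple[AnnModel, list[float]]:
    """Epochs of seeded-shuffle per-example updates.

    Returns the trained model and the per-epoch mean training loss trace.
    When `monitor` = (X_val, Y_val) is supplied, stops early once the
    monitoring loss fails to improve for `config.patience` epochs and restores
    the best weights.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if len(X) != len(Y):
        raise ValueError("X and Y row counts differ")
    model = model.copy()
    model.training_config = config
    rng = np.random.default_rng(config.shuffle_seed)
    trace: list[float] = []
    best_val = np.inf
    best_state: Optional[AnnModel] = None
    stale = 0
    for _ in range(config.epochs):
        order = rng.permutation(len(X))
        for idx in order:
            backprop_step(model, X[idx], Y[idx], config)
        trace.append(_loss(model, X, Y, config.loss))
        if monitor is not None:
            val = _loss(model, monitor[0], monitor[1], config.loss)
            if val < best_val - 1e-12:
                best_val, best_state, stale = val, model.copy(), 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
    if monitor is not None and best_state is not None:
        best_state.training_config = config
        return best_state, trace
    return model, trace


def predict_profile(model: AnnModel, mol: Molecule,
                    config: Optional[DescriptorConfig] = None) -> dict[str, float]:
    """Featurize -> normalize -> forward; scores keyed by kinase id."""
    cfg = config or default_config()
    fv = featurize(mol, cfg)
    if len(fv.values) != model.n_in:
        raise ValueError(
            f"descriptor layout length {len(fv.values)} != model inputs {model.n_in}"
        )
    x = fv.values[None, :]
    if model.normalizer is not None:
        x = model.normalizer.transform(x)
    scores = forward(model, x)[0]
    ids = model.kinase_ids or [f"task_{i}" for i in range(model.n_out)]
    return dict(zip(ids, scores.tolist()))


def save_model(model: AnnModel, path: Union[str, Path]) -> None:
    """Serialize to a versioned JSON document; reload is bit-stable."""
    doc = {
        "format": "kinsel-ann/1",
        "W1": model.W1.tolist(), "b1": model.b1.tolist(),
        "W2": model.W2.tolist(), "b2": model.b2.tolist(),
        "normalizer": model.normalizer.to_dict() if model.normalizer else None,
        "kinase_ids": model.kinase_ids,
        "seed": model.seed,
        "training_config": asdict(model.training_config)
        if model.training_config else None,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def load_model(path: Union[str, Path]) -> AnnModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "kinsel-ann/1":
        raise ValueError("unrecognized model file format")
    return AnnModel(
        W1=np.array(doc["W1"]), b1=np.array(doc["b1"]),
        W2=np.array(doc["W2"]), b2=np.array(doc["b2"]),
        normalizer=Normalizer.from_dict(doc["normalizer"])
        if doc["normalizer"] else None,
        kinase_ids=doc["kinase_ids"],
        seed=doc["seed"],
        training_config=TrainingConfig(**doc["training_config"])
        if doc["training_config"] else None,
    )
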