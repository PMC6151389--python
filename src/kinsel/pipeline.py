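"""End-to-end helpers tying descriptors, dataset, and the network together."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .ann import AnnModel, TrainingConfig, forward, init_model, train
from .dataset import ActivityMatrix, binarize, fit_normalizer, split_folds

__all__ = ["train_panel_model", "cross_validate_scores"]


def train_panel_model(
    X: np.ndarray,
    activity: ActivityMatrix,
    cutoff_uM: float,
    seed: int,
    n_hidden: int = 32,
    config: Optional[TrainingConfig] = None,
    monitor_idx: Optional[np.ndarray] = None,
) -> AnnModel:
    """Fit one multi-task model on all compounds at one Kd cutoff.

    Features are z-scored with statistics from the training rows; the fitted
    normalizer travels with the model.  `monitor_idx` rows, when given, are
    held out of the updates and used for early stopping.
    """
    cfg = config or TrainingConfig(shuffle_seed=seed)
    labels = binarize(activity, cutoff_uM).labels
    train_idx = np.arange(len(X))
    monitor = None
    if monitor_idx is not None:
        train_idx = np.setdiff1d(train_idx, monitor_idx)
    norm = fit_normalizer(X[train_idx])
    Z = norm.transform(X)
    if monitor_idx is not None:
        monitor = (Z[monitor_idx], labels[monitor_idx])
    model = init_model(X.shape[1], n_hidden, labels.shape[1], seed=seed,
                       kinase_ids=list(activity.kinases))
    model, _ = train(model, Z[train_idx], labels[train_idx], cfg, monitor=monitor)
    model.normalizer = norm
    return model


def cross_validate_scores(
    X: np.ndarray,
    activity: ActivityMatrix,
    cutoff_uM: float,
    k_folds: int = 5,
    seed: int = 0,
    n_hidden: int = 32,
    config: Optional[TrainingConfig] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Compound-level k-fold CV; returns (out-of-fold score matrix, fold ids).

    Each fold's model is trained on the other folds only (normalizer
    included), so every score is an honest held-out prediction.
    """
    labels = binarize(activity, cutoff_uM).labels
    folds = split_folds(len(X), k_folds, seed)
    scores = np.zeros_like(labels, dtype=float)
    for f in range(k_folds):
        test = folds == f
        norm = fit_normalizer(X[~test])
        model = init_model(X.shape[1], n_hidden, labels.shape[1], seed=seed + f,
                           kinase_ids=list(activity.kinases))
        cfg = config or TrainingConfig(shuffle_seed=seed + f)
        model, _ = train(model, norm.transform(X[~test]), labels[~test], cfg)
        scores[test] = forward(model, norm.transform(X[test]))
    return scores, folds
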