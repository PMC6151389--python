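"""Evaluation of panel activity predictions.

Covers pooled confusion-matrix metrics (sensitivity, selectivity, accuracy,
Matthews correlation, predictive values), ROC curves and AUC per kinase with
quartile summaries, per-kinase decision thresholds chosen by maximum MCC,
model comparison by the paired signed-rank test on per-kinase AUCs, a Fisher
exact comparison against a coin-flip predictor, and activity-matrix
difference maps.

MCC is computed as

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with a zero denominator flagged and reported as 0 (the usual convention for a
degenerate margin).  All other metrics with a zero denominator are reported
as NaN with a flag rather than silently zeroed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .dataset import LabelMatrix

__all__ = [
    "ConfusionCounts", "MetricsReport", "RocCurve",
    "confusion", "metrics", "roc", "per_kinase_summary", "choose_threshold",
    "paired_rank_test", "unpaired_rank_test", "fisher_exact_2x2",
    "fisher_vs_random", "diff_matrix",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def actives(self) -> int:
        return self.tp + self.fn

    @property
    def inactives(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricsReport:
    """Derived binary-classification metrics.

    sen/sel/acc/ppv/npv are fractions in [0, 1]; mcc in [-1, 1].  Metrics
    whose denominator is zero are NaN and listed in `undefined` (mcc is set
    to 0 and flagged instead).
    """

    counts: ConfusionCounts
    sen: float
    sel: float
    acc: float
    mcc: float
    ppv: float
    npv: float
    undefined: tuple[str, ...] = ()

    def as_percent_row(self) -> dict[str, float]:
        """Metrics formatted the way panel tables print them: ACC/SEN/SEL in
        percent, MCC/PPV/NPV as fractions, all at 2 decimals."""
        return {
            "MCC": round(self.mcc, 2),
            "ACC": round(self.acc * 100, 2),
            "SEN": round(self.sen * 100, 2),
            "SEL": round(self.sel * 100, 2),
            "PPV": round(self.ppv, 2),
            "NPV": round(self.npv, 2),
        }


def confusion(labels: np.ndarray, calls: np.ndarray) -> ConfusionCounts:
    """Count TP/FP/TN/FN from aligned binary vectors."""
    labels = np.asarray(labels).ravel()
    calls = np.asarray(calls).ravel()
    if labels.shape != calls.shape or labels.size == 0:
        raise ValueError("labels and calls must be equal-length, non-empty")
    return ConfusionCounts(
        tp=int(np.sum((labels == 1) & (calls == 1))),
        fp=int(np.sum((labels == 0) & (calls == 1))),
        tn=int(np.sum((labels == 0) & (calls == 0))),
        fn=int(np.sum((labels == 1) & (calls == 0))),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics(c: ConfusionCounts) -> MetricsReport:
    """All six derived metrics from one set of confusion counts."""
    if c.total == 0:
        raise ValueError("cannot compute metrics on all-zero counts")
    sen = _ratio(c.tp, c.tp + c.fn)
    sel = _ratio(c.tn, c.tn + c.fp)
    acc = (c.tp + c.tn) / c.total
    ppv = _ratio(c.tp, c.tp + c.fp)
    npv = _ratio(c.tn, c.tn + c.fn)
    undefined = []
    den = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if den > 0:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(den)
    else:
        mcc = 0.0
        undefined.append("mcc")
    for name, v in (("sen", sen), ("sel", sel), ("ppv", ppv), ("npv", npv)):
        if math.isnan(v):
            undefined.append(name)
    return MetricsReport(counts=c, sen=sen, sel=sel, acc=acc, mcc=mcc,
                         ppv=ppv, npv=npv, undefined=tuple(undefined))


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC by descending-threshold sweep (ties grouped) and trapezoidal AUC.

    The AUC equals the Mann-Whitney U statistic divided by n_pos * n_neg with
    ties counted one half.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    npos = int(np.sum(labels == 1))
    nneg = int(np.sum(labels == 0))
    if npos == 0 or nneg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


@dataclass
class PerKinaseSummary:
    kinase_ids: list[str]
    auc: np.ndarray  # NaN where a kinase column is single-class
    skipped: list[str]
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    whisker_low: float
    whisker_high: float


def per_kinase_summary(scores: np.ndarray, labels: np.ndarray,
                       kinase_ids: Optional[list[str]] = None) -> PerKinaseSummary:
    """Per-kinase-column AUC plus box-plot quartile summary.

    Single-class columns are skipped (AUC NaN) and listed.  Whiskers are the
    extreme AUCs within 1.5x IQR of the box edges.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.atleast_2d(np.asarray(labels))
    if scores.shape != labels.shape:
        raise ValueError("score and label matrices must align")
    ids = kinase_ids or [f"task_{j}" for j in range(scores.shape[1])]
    aucs = np.full(scores.shape[1], np.nan)
    skipped = []
    for j in range(scores.shape[1]):
        col = labels[:, j]
        if 0 < col.sum() < len(col):
            aucs[j] = roc(scores[:, j], col).auc
        else:
            skipped.append(ids[j])
    valid = aucs[~np.isnan(aucs)]
    if valid.size == 0:
        raise ValueError("no kinase column has both classes")
    q1, med, q3 = np.percentile(valid, [25, 50, 75])
    iqr = q3 - q1
    in_low = valid[valid >= q1 - 1.5 * iqr]
    in_high = valid[valid <= q3 + 1.5 * iqr]
    return PerKinaseSummary(
        kinase_ids=ids, auc=aucs, skipped=skipped,
        minimum=float(valid.min()), q1=float(q1), median=float(med),
        q3=float(q3), maximum=float(valid.max()),
        whisker_low=float(in_low.min()), whisker_high=float(in_high.max()),
    )


def choose_threshold(scores: np.ndarray, labels: np.ndarray,
                     criterion: str = "mcc") -> tuple[float, float]:
    """Pick the per-kinase decision threshold maximizing the criterion.

    Candidates are midpoints of consecutive distinct sorted scores (plus one
    above the maximum); ties on the criterion break toward the higher
    threshold, i.e. fewer positive calls.  Returns (threshold, criterion
    value).  A call is positive when score >= threshold.
    """
    if criterion != "mcc":
        raise ValueError(f"unsupported criterion {criterion!r}")
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if 0 == labels.sum() or labels.sum() == len(labels):
        raise ValueError("threshold undefined: both classes must be present")
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.concatenate([mids, [distinct[-1] + 1.0]])
    best_thr, best_val = candidates[0], -np.inf
    for thr in candidates:
        calls = (scores >= thr).astype(int)
        val = metrics(confusion(labels, calls)).mcc
        if val > best_val or (val == best_val and thr > best_thr):
            best_thr, best_val = float(thr), float(val)
    return best_thr, best_val


def paired_rank_test(auc_a: np.ndarray, auc_b: np.ndarray) -> tuple[float, float]:
    """Wilcoxon signed-rank test on per-kinase AUC differences.

    Zero differences are dropped; the null is enumerated exactly for n <= 12
    remaining pairs and approximated normally above.  Returns (statistic,
    two-sided p).  All-zero differences give p = 1.
    """
    a = np.asarray(auc_a, dtype=float).ravel()
    b = np.asarray(auc_b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need equal-length paired vectors with n >= 5")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        return 0.0, 1.0
    method = "exact" if nz.size <= 12 else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                         method=method)
    return float(res.statistic), float(res.pvalue)


def unpaired_rank_test(auc_a: np.ndarray, auc_b: np.ndarray) -> tuple[float, float]:
    """Unpaired Mann-Whitney U, for completeness alongside the paired test."""
    res = stats.mannwhitneyu(auc_a, auc_b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric enumeration)."""
    _, p = stats.fisher_exact(np.asarray(table, dtype=int), alternative="two-sided")
    return float(p)


def fisher_vs_random(c: ConfusionCounts) -> tuple[float, np.ndarray]:
    """Fisher exact comparison of the model against a coin-flip predictor.

    The 2x2 table opposes correct vs incorrect calls for the model
    (TP+TN vs FP+FN) and for a random model labeling 50% of the same cases
    positive, which is right on half the actives and half the inactives —
    total/2 correct.  Returns (two-sided p, table).
    """
    if c.total == 0:
        raise ValueError("empty confusion counts")
    half = c.total // 2
    table = np.array(
        [[c.tp + c.tn, c.fp + c.fn], [half, c.total - half]]
    )
    return fisher_exact_2x2(table), table


def diff_matrix(expected: LabelMatrix, predicted: LabelMatrix):
    """Cellwise comparison of experimental and predicted label matrices.

    Returns (diff, counts): diff holds 0 = correct, +1 = false positive,
    -1 = false negative; counts is {'correct', 'fp', 'fn'} and always sums to
    the number of cells.
    """
    if expected.labels.shape != predicted.labels.shape:
        raise ValueError("label matrices must have the same shape")
    if expected.compounds != predicted.compounds or expected.kinases != predicted.kinases:
        raise ValueError("label matrices must share compound/kinase orderings")
    diff = predicted.labels - expected.labels
    counts = {
        "correct": int(np.sum(diff == 0)),
        "fp": int(np.sum(diff == 1)),
        "fn": int(np.sum(diff == -1)),
    }
    return diff, counts
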