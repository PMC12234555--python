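"""Segmentation metrics: confusion counts, Dice, IoU, precision, recall,
normal-approximation confidence intervals and k-fold splitting.

All four scores are defined on binary masks. X and Y denote the predicted
and ground-truth positive pixel sets:

    Dice      = 2|X∩Y| / (|X| + |Y|)
    IoU       = |X∩Y| / |X∪Y|
    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)

Degenerate denominators (both masks empty, no predicted positives, no true
positives) return 1.0 by convention — perfect agreement about absence —
with a logged warning.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = ["ConfusionCounts", "SegMetricsRecord", "MetricSummary",
           "confusion_counts", "dice", "iou", "precision", "recall",
           "evaluate_pair", "mean_ci", "kfold_split",
           "write_score_table", "read_score_table", "summarize"]

SCORE_COLUMNS = ("id", "dice", "iou", "precision", "recall")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class SegMetricsRecord:
    id: str
    dice: float
    iou: float
    precision: float
    recall: float


@dataclass(frozen=True)
class MetricSummary:
    mean: float
    ci_low: float
    ci_high: float
    n: int


def _check_masks(pred: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    for name, m in (("pred", pred), ("gt", gt)):
        vals = np.unique(m)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{name} mask contains values outside {{0,1}}")
    return pred.astype(bool), gt.astype(bool)


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Pixelwise TP/FP/FN/TN tally of a predicted vs ground-truth mask."""
    p, g = _check_masks(pred, gt)
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        logger.warning("undefined %s (0/0); returning 1.0 by convention", what)
        return 1.0
    return num / den


def dice(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice overlap 2|X∩Y|/(|X|+|Y|); 1.0 when both masks are empty."""
    p, g = _check_masks(pred, gt)
    inter = int(np.count_nonzero(p & g))
    return _ratio(2 * inter, int(p.sum()) + int(g.sum()), "dice")


def iou(pred: np.ndarray, gt: np.ndarray) -> float:
    """Jaccard index |X∩Y|/|X∪Y|; 1.0 when both masks are empty."""
    p, g = _check_masks(pred, gt)
    inter = int(np.count_nonzero(p & g))
    union = int(np.count_nonzero(p | g))
    return _ratio(inter, union, "iou")


def precision(counts: ConfusionCounts) -> float:
    return _ratio(counts.TP, counts.TP + counts.FP, "precision")


def recall(counts: ConfusionCounts) -> float:
    return _ratio(counts.TP, counts.TP + counts.FN, "recall")


def evaluate_pair(pred: np.ndarray, gt: np.ndarray,
                  id: str = "") -> SegMetricsRecord:
    """All four scores for one image."""
    c = confusion_counts(pred, gt)
    return SegMetricsRecord(id=id, dice=dice(pred, gt), iou=iou(pred, gt),
                            precision=precision(c), recall=recall(c))


def mean_ci(scores, level: float = 0.95, method: str = "normal",
            n_boot: int = 10000, seed: int = 0) -> MetricSummary:
    """Mean with a symmetric confidence interval over per-image scores.

    ``normal``: mean ± z·sd/√n with the sample standard deviation.
    ``bootstrap``: percentile bootstrap, symmetrised about the mean.
    Intervals are clipped to [0, 1].
    """
    scores = np.asarray(list(scores), dtype=float)
    n = scores.size
    if n < 2:
        raise ValueError("need at least 2 scores for an interval")
    m = float(scores.mean())
    if method == "normal":
        z = stats.norm.ppf(0.5 + level / 2)
        half = float(z * scores.std(ddof=1) / np.sqrt(n))
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        means = rng.choice(scores, size=(n_boot, n), replace=True).mean(axis=1)
        lo, hi = np.quantile(means, [0.5 - level / 2, 0.5 + level / 2])
        half = float(max(m - lo, hi - m))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return MetricSummary(mean=m, ci_low=max(0.0, m - half),
                         ci_high=min(1.0, m + half), n=n)


def kfold_split(ids, k: int = 5, seed: int = 0) -> list[list]:
    """Deterministically partition ids into k disjoint folds (sizes ±1)."""
    ids = list(ids)
    if k > len(ids):
        raise ValueError("k cannot exceed the number of ids")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [[ids[i] for i in test_idx] for _, test_idx in kf.split(ids)]


def write_score_table(records, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SCORE_COLUMNS)
        for r in records:
            w.writerow([r.id, f"{r.dice:.6f}", f"{r.iou:.6f}",
                        f"{r.precision:.6f}", f"{r.recall:.6f}"])


def read_score_table(path) -> list[SegMetricsRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(SegMetricsRecord(
                id=row["id"], dice=float(row["dice"]), iou=float(row["iou"]),
                precision=float(row["precision"]), recall=float(row["recall"])))
    return out


def summarize(records, level: float = 0.95) -> dict[str, MetricSummary]:
    """Per-metric mean and CI over a list of SegMetricsRecord."""
    return {metric: mean_ci([getattr(r, metric) for r in records], level)
            for metric in ("dice", "iou", "precision", "recall")}
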