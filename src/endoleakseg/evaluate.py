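"""Reader-style evaluation: confusion metrics, slice-level ROC/AUC, bootstrap SD.

Accuracy/precision/recall/F1 are reported as percentages.  AUC is computed by
trapezoidal integration of the ROC over all score thresholds, which equals the
pairwise-concordance (Mann–Whitney) statistic with ties counted half.  The
bootstrap resamples whole cases with replacement and reports the SD of the
resampled accuracies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    """Percent-scale metrics; undefined ratios are NaN, never silently 0."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: Optional[float] = None
    bootstrap_sd: Optional[float] = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def confusion(predicted: Sequence[bool], truth: Sequence[bool]) -> ConfusionCounts:
    """Standard 2×2 tally of predicted vs true binary flags."""
    pred = np.asarray(predicted, dtype=bool)
    true = np.asarray(truth, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError("predicted and true flags must have equal length")
    if pred.size == 0:
        raise ValueError("cannot tally an empty input")
    return ConfusionCounts(tp=int((pred & true).sum()),
                           fp=int((pred & ~true).sum()),
                           tn=int((~pred & ~true).sum()),
                           fn=int((~pred & true).sum()))


def metrics(counts: ConfusionCounts) -> MetricReport:
    """accuracy, precision, recall, F1 as percentages.

    precision is NaN when nothing was flagged positive; recall is NaN when no
    true positives exist; F1 is NaN when either constituent is.
    """
    if counts.total < 1:
        raise ValueError("empty confusion")
    acc = 100.0 * (counts.tp + counts.tn) / counts.total
    prec = math.nan if counts.tp + counts.fp == 0 else \
        100.0 * counts.tp / (counts.tp + counts.fp)
    rec = math.nan if counts.tp + counts.fn == 0 else \
        100.0 * counts.tp / (counts.tp + counts.fn)
    if math.isnan(prec) or math.isnan(rec) or prec + rec == 0:
        f1 = math.nan
    else:
        f1 = 2 * prec * rec / (prec + rec)
    return MetricReport(accuracy=acc, precision=prec, recall=rec, f1=f1)


def roc_curve(scores: Sequence[float], truth: Sequence[bool]
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC points (fpr, tpr, thresholds) over all distinct score cuts."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=bool)
    if s.shape != t.shape:
        raise ValueError("scores and flags must have equal length")
    n_pos, n_neg = int(t.sum()), int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    order = np.argsort(-s, kind="stable")
    s, t = s[order], t[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tps = np.cumsum(t)[distinct]
    fps = np.cumsum(~t)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thr = np.r_[np.inf, s[distinct]]
    return fpr, tpr, thr


def roc_auc(scores: Sequence[float], truth: Sequence[bool]) -> float:
    """Area under the ROC by trapezoidal integration (ties counted half)."""
    fpr, tpr, _ = roc_curve(scores, truth)
    return float(np.trapezoid(tpr, fpr))


def bootstrap_sd(correct: Sequence[bool], n_boot: int = 1000,
                 seed: int = 0) -> float:
    """SD (percentage points) of accuracy over case resamples with replacement."""
    flags = np.asarray(correct, dtype=bool)
    if flags.size == 0:
        raise ValueError("need at least one case")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, flags.size, size=(n_boot, flags.size))
    accs = flags[idx].mean(axis=1)
    return float(100.0 * accs.std())
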