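"""Macro-averaged multiclass metrics with brute-force-verifiable definitions.

All metrics are computed per class and averaged without support weighting,
so rare phenotypes count as much as common ones:

* accuracy — fraction of correct predictions;
* macro F1 — unweighted mean of per-class F1; a class absent from both
  predictions and truth contributes 0 (conservative convention);
* macro AUC — one-vs-rest rank-based (Mann-Whitney) AUC per class, ties
  receiving half credit; classes without both positives and negatives are
  skipped;
* macro AUPRC — per-class average precision (step-wise integral of the
  precision-recall curve); classes without positives are skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "MetricReport",
    "accuracy",
    "macro_f1",
    "macro_auc",
    "macro_auprc",
    "confusion_matrix",
    "evaluate_task",
]


def accuracy(pred: Sequence, true: Sequence) -> float:
    pred, true = np.asarray(pred), np.asarray(true)
    if len(pred) != len(true):
        raise ValueError("pred and true must have equal length")
    if len(pred) == 0:
        raise ValueError("empty input")
    return float((pred == true).mean())


def _binary_f1(pred_pos: np.ndarray, true_pos: np.ndarray) -> float:
    tp = int((pred_pos & true_pos).sum())
    fp = int((pred_pos & ~true_pos).sum())
    fn = int((~pred_pos & true_pos).sum())
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def macro_f1(pred: Sequence, true: Sequence, classes: Iterable) -> float:
    """Unweighted mean of one-vs-rest F1 over the fixed class vocabulary."""
    pred, true = np.asarray(pred), np.asarray(true)
    scores = [_binary_f1(pred == c, true == c) for c in classes]
    if not scores:
        raise ValueError("empty class vocabulary")
    return float(np.mean(scores))


def _binary_auc(scores: np.ndarray, pos: np.ndarray) -> float:
    """Rank-based AUC: P(score_pos > score_neg) + 0.5 P(equal)."""
    ranks = rankdata(scores)  # midranks handle ties exactly
    n_pos = int(pos.sum())
    n_neg = len(pos) - n_pos
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def macro_auc(scores: np.ndarray, true: Sequence, classes: Sequence) -> float:
    """One-vs-rest AUC per class (column of ``scores``), macro-averaged over
    classes that have at least one positive and one negative."""
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    true = np.asarray(true)
    vals = []
    for j, c in enumerate(classes):
        pos = true == c
        if pos.all() or not pos.any():
            warnings.warn(f"class {c!r} lacks positives or negatives; skipped in AUC", stacklevel=2)
            continue
        vals.append(_binary_auc(scores[:, j], pos))
    return float(np.mean(vals)) if vals else float("nan")


def _average_precision(scores: np.ndarray, pos: np.ndarray) -> float:
    """Step-wise AP: sum over distinct thresholds of (recall step) x precision."""
    order = np.argsort(-scores, kind="stable")
    s, p = scores[order], pos[order].astype(np.float64)
    n_pos = p.sum()
    tp = np.cumsum(p)
    fp = np.cumsum(1.0 - p)
    # evaluate only at the last index of each tied-score block
    last_of_block = np.append(s[1:] != s[:-1], True)
    tp_b, fp_b = tp[last_of_block], fp[last_of_block]
    precision = tp_b / (tp_b + fp_b)
    recall = tp_b / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(((recall - prev_recall) * precision).sum())


def macro_auprc(scores: np.ndarray, true: Sequence, classes: Sequence) -> float:
    """Per-class average precision, macro-averaged over classes with >=1 positive."""
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    true = np.asarray(true)
    vals = []
    for j, c in enumerate(classes):
        pos = true == c
        if not pos.any():
            warnings.warn(f"class {c!r} has no positives; skipped in AUPRC", stacklevel=2)
            continue
        vals.append(_average_precision(scores[:, j], pos))
    return float(np.mean(vals)) if vals else float("nan")


def confusion_matrix(pred: Sequence, true: Sequence, classes: Sequence, normalize: bool = False) -> np.ndarray:
    """Rows are true classes, columns predicted; optionally row-normalized
    (nonempty rows then sum to one)."""
    pred, true = np.asarray(pred), np.asarray(true)
    index = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((len(index), len(index)), dtype=np.float64)
    for p, t in zip(pred, true):
        mat[index[t], index[p]] += 1
    if normalize:
        sums = mat.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        mat = mat / sums
    return mat


@dataclass
class MetricReport:
    accuracy: float
    macro_f1: float
    macro_auc: float
    macro_auprc: float
    per_class: pd.DataFrame           # F1, AUC, AUPRC, support per class
    confusion: np.ndarray
    confusion_normalized: np.ndarray

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "macro_auc": self.macro_auc,
            "macro_auprc": self.macro_auprc,
            "per_class": self.per_class.to_dict(orient="index"),
            "confusion": self.confusion.tolist(),
            "confusion_normalized": self.confusion_normalized.tolist(),
        }


def evaluate_task(
    pred: Sequence,
    true: Sequence,
    scores: np.ndarray,
    classes: Sequence,
) -> MetricReport:
    """Full metric report for one task from hard labels and class scores."""
    pred, true = np.asarray(pred), np.asarray(true)
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    classes = list(classes)
    rows = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, c in enumerate(classes):
            pos = true == c
            rows[c] = {
                "f1": _binary_f1(pred == c, pos),
                "auc": _binary_auc(scores[:, j], pos) if (pos.any() and not pos.all()) else float("nan"),
                "auprc": _average_precision(scores[:, j], pos) if pos.any() else float("nan"),
                "support": int(pos.sum()),
            }
        return MetricReport(
            accuracy=accuracy(pred, true),
            macro_f1=macro_f1(pred, true, classes),
            macro_auc=macro_auc(scores, true, classes),
            macro_auprc=macro_auprc(scores, true, classes),
            per_class=pd.DataFrame.from_dict(rows, orient="index"),
            confusion=confusion_matrix(pred, true, classes),
            confusion_normalized=confusion_matrix(pred, true, classes, normalize=True),
        )
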