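"""Unsupervised clustering evaluation against held-back labels.

Fitted HMM states carry no activity names, so predicted state indices are
first aligned to true labels by an accuracy-maximizing one-to-one
assignment (Hungarian algorithm on the contingency matrix); surplus states
beyond the number of labels map to their modal label.  The aligned labels
are then scored with accuracy, precision, recall and F1, where precision
and recall are computed one-vs-rest per class and averaged (macro by
default; micro and weighted also available).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "ConfusionCounts",
    "match_clusters",
    "apply_mapping",
    "confusion_counts",
    "metrics",
    "evaluate",
    "format_report",
]


@dataclass
class ConfusionCounts:
    """One-vs-rest confusion counts per class.

    tp, tn, fp, fn are arrays over classes; for every class the four counts
    sum to ``total``.
    """

    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    classes: np.ndarray

    @property
    def total(self) -> int:
        return int(self.tp[0] + self.tn[0] + self.fp[0] + self.fn[0])

    @property
    def support(self) -> np.ndarray:
        return self.tp + self.fn


def match_clusters(true_labels: np.ndarray, pred_states: np.ndarray) -> dict[int, int]:
    """Accuracy-maximizing mapping from predicted state index to true label.

    Builds the contingency matrix and solves the optimal one-to-one
    assignment; when there are more states than labels, unmatched states
    fall back to their modal true label.
    """
    t = np.asarray(true_labels)
    p = np.asarray(pred_states)
    if t.size == 0 or p.size == 0:
        raise ValueError("empty label vectors")
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    labels = np.unique(t)
    states = np.unique(p)
    cont = np.zeros((states.size, labels.size), dtype=int)
    for si, s in enumerate(states):
        sel = t[p == s]
        for li, l in enumerate(labels):
            cont[si, li] = int((sel == l).sum())
    rows, cols = linear_sum_assignment(cont, maximize=True)
    mapping = {int(states[r]): int(labels[c]) for r, c in zip(rows, cols)}
    for si, s in enumerate(states):
        if int(s) not in mapping:
            mapping[int(s)] = int(labels[cont[si].argmax()])
    return mapping


def apply_mapping(pred_states: np.ndarray, mapping: dict[int, int]) -> np.ndarray:
    return np.asarray([mapping[int(s)] for s in np.asarray(pred_states)])


def confusion_counts(true_labels: np.ndarray, pred_labels: np.ndarray) -> ConfusionCounts:
    """One-vs-rest TP/TN/FP/FN per class present in either vector."""
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    if t.size == 0:
        raise ValueError("empty label vectors")
    classes = np.unique(np.concatenate([t, p]))
    tp = np.array([int(((t == c) & (p == c)).sum()) for c in classes])
    fp = np.array([int(((t != c) & (p == c)).sum()) for c in classes])
    fn = np.array([int(((t == c) & (p != c)).sum()) for c in classes])
    tn = t.size - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn, classes=classes)


def metrics(counts: ConfusionCounts, average: str = "macro") -> dict[str, float]:
    """Accuracy, precision, recall and F1 from confusion counts.

    Accuracy is the multi-class agreement rate (sum of per-class TP over
    total).  Precision/recall are one-vs-rest per class then averaged per
    ``average`` in {macro, micro, weighted}; F1 = 2PR/(P+R) on the averaged
    precision and recall.  Classes never predicted contribute precision 0
    with a warning.
    """
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    tp, fp, fn = counts.tp.astype(float), counts.fp.astype(float), counts.fn.astype(float)
    pred_pos = tp + fp
    if (pred_pos == 0).any():
        warnings.warn(
            f"classes never predicted: {counts.classes[pred_pos == 0].tolist()}; precision set to 0"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        prec_c = np.where(pred_pos > 0, tp / np.where(pred_pos > 0, pred_pos, 1.0), 0.0)
        actual_pos = tp + fn
        rec_c = np.where(actual_pos > 0, tp / np.where(actual_pos > 0, actual_pos, 1.0), 0.0)
    accuracy = tp.sum() / counts.total
    if average == "macro":
        precision, recall = prec_c.mean(), rec_c.mean()
    elif average == "micro":
        precision = tp.sum() / max(pred_pos.sum(), 1.0)
        recall = tp.sum() / max((tp + fn).sum(), 1.0)
    elif average == "weighted":
        w = counts.support / counts.support.sum()
        precision, recall = float(prec_c @ w), float(rec_c @ w)
    else:
        raise ValueError(f"unknown averaging mode: {average!r}")
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return {
        "accuracy": float(accuracy),
        "precision": float(precision),
        "recall": float(recall),
        "f1": float(f1),
    }


def evaluate(
    true_labels: np.ndarray, pred_states: np.ndarray, average: str = "macro"
) -> dict[str, float]:
    """Hungarian-match predicted states to labels, then score."""
    mapping = match_clusters(true_labels, pred_states)
    mapped = apply_mapping(pred_states, mapping)
    return metrics(confusion_counts(true_labels, mapped), average=average)


def format_report(results: dict[str, dict[str, float]]) -> str:
    """Aligned plain-text table (method x metric, percentages to 2 decimals)."""
    header = f"{'Method':<12}{'Accuracy':>10}{'Precision':>11}{'Recall':>9}{'F1-Score':>10}"
    lines = [header]
    for name, m in results.items():
        lines.append(
            f"{name:<12}{100 * m['accuracy']:>10.2f}{100 * m['precision']:>11.2f}"
            f"{100 * m['recall']:>9.2f}{100 * m['f1']:>10.2f}"
        )
    return "\n".join(lines)


def write_report(path, results: dict[str, dict[str, float]]) -> None:
    with open(path, "w") as fh:
        json.dump(results, fh, indent=1)
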