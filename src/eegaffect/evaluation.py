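"""Confusion-matrix metrics, ROC/PR curves and per-dimension reports.

Metrics are the standard four on the 2x2 table with "high" as the positive
class: accuracy (TP+TN)/total, precision TP/(TP+FP), recall TP/(TP+FN) and
the F-score as their harmonic mean, reported as percentages.  Because
published tables mix formatting conventions, the rounding policy (half-up
rounding vs truncation) and decimal count are explicit arguments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .io_deap import HIGH


class MetricsFlag:
    """Sentinel notes attached when a denominator vanished."""


def confusion(y_true: np.ndarray, y_pred: np.ndarray,
              positive_class: int = HIGH) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) counts with ``positive_class`` as positive."""
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred lengths differ")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    tp = int(np.sum(pos_t & pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    return tp, tn, fp, fn


def _format(x: float, rounding: str, decimals: int) -> float:
    scale = 10.0**decimals
    if rounding == "truncate":
        return math.floor(x * scale + 1e-9) / scale
    if rounding == "round":  # half-up
        return math.floor(x * scale + 0.5) / scale
    raise ValueError("rounding must be 'round' or 'truncate'")


def metrics(tp: int, tn: int, fp: int, fn: int,
            rounding: str = "round", decimals: int = 4) -> dict[str, float]:
    """Accuracy, precision, recall and F-score as formatted percentages.

    Zero-denominator cases (no predicted or no actual positives) report 0
    for the affected metric and list it under ``"flags"``.
    """
    for c in (tp, tn, fp, fn):
        if c < 0:
            raise ValueError("counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion table")
    flags = []
    accuracy = (tp + tn) / total
    if tp + fp == 0:
        precision = 0.0
        flags.append("precision")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 0.0
        flags.append("recall")
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f_score = 0.0
        flags.append("f_score")
    else:
        f_score = 2 * precision * recall / (precision + recall)
    out = {
        "accuracy": _format(100 * accuracy, rounding, decimals),
        "precision": _format(100 * precision, rounding, decimals),
        "recall": _format(100 * recall, rounding, decimals),
        "f_score": _format(100 * f_score, rounding, decimals),
    }
    out["flags"] = flags
    return out


def roc_pr_curves(y_true: np.ndarray, scores: np.ndarray
                  ) -> tuple[list[tuple[float, float]], list[tuple[float, float]], float]:
    """ROC points (FPR, TPR), PR points (recall, precision) and trapezoid AUC.

    One point per unique score threshold, swept descending, anchored at
    (0, 0) and (1, 1) on the ROC side.
    """
    y_true = np.asarray(y_true).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if y_true.size != scores.size:
        raise ValueError("length mismatch")
    pos = y_true == HIGH
    P = int(pos.sum())
    N = y_true.size - P
    if P == 0 or N == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_pos = pos[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_pos)
    fps = np.cumsum(~sorted_pos)
    # keep the last index of each unique score (threshold = that score)
    last = np.r_[np.flatnonzero(np.diff(sorted_scores)), y_true.size - 1]
    roc = [(0.0, 0.0)] + [(fps[i] / N, tps[i] / P) for i in last]
    if roc[-1] != (1.0, 1.0):
        roc.append((1.0, 1.0))
    pr = [(tps[i] / P, tps[i] / (tps[i] + fps[i])) for i in last]
    fpr = np.array([p[0] for p in roc])
    tpr = np.array([p[1] for p in roc])
    auc = float(np.trapezoid(tpr, fpr))
    return roc, pr, auc


@dataclass
class EvaluationReport:
    """Everything measured for one affect dimension on one test set."""

    dimension: str
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f_score: float
    auc: float
    roc_points: list = field(default_factory=list)
    pr_points: list = field(default_factory=list)
    flags: list = field(default_factory=list)

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "EvaluationReport":
        d = json.loads(Path(path).read_text())
        d["roc_points"] = [tuple(p) for p in d["roc_points"]]
        d["pr_points"] = [tuple(p) for p in d["pr_points"]]
        return cls(**d)


def evaluate(dimension: str, y_true: np.ndarray, y_pred: np.ndarray,
             scores: Optional[np.ndarray] = None,
             rounding: str = "round", decimals: int = 4) -> EvaluationReport:
    """Full report: confusion counts, percentage metrics and (optionally) curves."""
    tp, tn, fp, fn = confusion(y_true, y_pred)
    m = metrics(tp, tn, fp, fn, rounding, decimals)
    roc, pr, auc = [], [], float("nan")
    if scores is not None and np.unique(np.asarray(y_true)).size == 2:
        roc, pr, auc = roc_pr_curves(y_true, scores)
    return EvaluationReport(
        dimension=dimension, tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=m["accuracy"], precision=m["precision"],
        recall=m["recall"], f_score=m["f_score"], auc=auc,
        roc_points=roc, pr_points=pr, flags=m["flags"],
    )
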