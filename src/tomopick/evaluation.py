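"""Particle-picking metrics: tolerance-based matching and precision/recall/F1.

Predicted pick coordinates are matched one-to-one to ground-truth
centers: predictions are visited in descending score (input order when
unscored) and each takes the nearest still-unmatched truth center within
the Euclidean tolerance. Matched predictions are true positives,
unmatched predictions false positives, unmatched truths false negatives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np


class EvaluationError(ValueError):
    """Raised on invalid metric inputs."""


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    tolerance: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


def match_predictions(
    pred_centers: Sequence[Sequence[float]] | np.ndarray,
    truth_centers: Sequence[Sequence[float]] | np.ndarray,
    tol: float,
    scores: Optional[Sequence[float]] = None,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of predictions to truth centers.

    Returns ``(TP, FP, FN)``. Greedy matching by descending score equals
    the optimal assignment whenever picks are farther than ``tol`` from
    each other, which holds for NMS output with radius >= tol.
    """
    if tol <= 0:
        raise EvaluationError("matching tolerance must be positive")
    pred = np.asarray(pred_centers, dtype=float).reshape(-1, 3)
    truth = np.asarray(truth_centers, dtype=float).reshape(-1, 3)
    if scores is not None:
        if len(scores) != len(pred):
            raise EvaluationError("scores length must match predictions")
        order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
        pred = pred[order]

    matched = np.zeros(len(truth), dtype=bool)
    tp = 0
    for p in pred:
        if not len(truth):
            break
        d = np.linalg.norm(truth - p, axis=1)
        d[matched] = np.inf
        j = int(np.argmin(d)) if len(d) else -1
        if j >= 0 and d[j] <= tol:
            matched[j] = True
            tp += 1
    fp = len(pred) - tp
    fn = len(truth) - tp
    return tp, fp, fn


def precision_recall_f1(tp: int, fp: int, fn: int,
                        tolerance: float = float("nan")) -> EvalResult:
    """Compute the standard picking metrics from match counts.

    Degenerate conventions: precision is 0 with no predictions; recall
    is 1 when both truth and predictions are empty, else 0 with an empty
    truth set; F1 is 0 when precision + recall is 0.
    """
    if min(tp, fp, fn) < 0:
        raise EvaluationError("counts must be non-negative")
    n_pred = tp + fp
    n_truth = tp + fn
    precision = tp / n_pred if n_pred else 0.0
    if n_truth:
        recall = tp / n_truth
    else:
        recall = 1.0 if n_pred == 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return EvalResult(tp, fp, fn, precision, recall, f1, tolerance)


def evaluate_picks(
    pred_centers,
    truth_centers,
    tol: float,
    scores: Optional[Sequence[float]] = None,
) -> EvalResult:
    """Convenience wrapper: match then score."""
    tp, fp, fn = match_predictions(pred_centers, truth_centers, tol, scores)
    return precision_recall_f1(tp, fp, fn, tolerance=tol)
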