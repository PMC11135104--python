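"""Centroid-distance prediction per block, weighted-vote fusion, metrics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)


@dataclass
class BlockPrediction:
    """Per-block centroid-distance predictions.

    ``scores`` holds the per-class continuous score used for ROC curves:
    the negative Euclidean distance to that class's centroid in component
    space (higher = closer).
    """

    classes: list[str]
    predicted: np.ndarray          # (n,) class labels
    scores: np.ndarray             # (n, K) negative distances

    def __post_init__(self) -> None:
        best = np.asarray(self.classes)[np.argmax(self.scores, axis=1)]
        if not np.array_equal(best, self.predicted):
            raise ValueError("predicted class must be the argmax of the scores")


def class_centroids(train_scores: np.ndarray, labels, classes: list[str]) -> np.ndarray:
    """Per-class mean of the training component scores, K x H."""
    labels = np.asarray(list(labels))
    out = np.empty((len(classes), train_scores.shape[1]))
    for k, c in enumerate(classes):
        mask = labels == c
        if not mask.any():
            raise ValueError(f"class {c!r} has no training samples")
        out[k] = train_scores[mask].mean(axis=0)
    return out


def predict_block(centroids: np.ndarray, test_scores: np.ndarray, classes: list[str]) -> BlockPrediction:
    """Assign each sample to the nearest class centroid (Euclidean).

    Ties broken by class order (argmin returns the first minimum).
    """
    d = np.linalg.norm(test_scores[:, None, :] - centroids[None, :, :], axis=2)
    idx = np.argmin(d, axis=1)
    return BlockPrediction(
        classes=list(classes),
        predicted=np.asarray(classes)[idx],
        scores=-d,
    )


def block_weights_from_scores(
    train_scores: dict[str, np.ndarray], Y_centered: np.ndarray
) -> dict[str, float]:
    """Weight per block: mean over components of the max-|correlation| between
    the block's training scores and the centered class-dummy columns."""
    weights = {}
    for b, T in train_scores.items():
        H = T.shape[1]
        acc = 0.0
        for h in range(H):
            t = T[:, h]
            if np.std(t) == 0:
                raise ValueError(f"zero-variance score vector in block {b!r}")
            r = [
                abs(np.corrcoef(t, Y_centered[:, k])[0, 1])
                for k in range(Y_centered.shape[1])
            ]
            acc += max(r)
        weights[b] = acc / H
    return weights


def block_weights(model) -> dict[str, float]:
    """Weights of a fitted model (correlation of training scores with the outcome)."""
    if not model.block_weights:
        raise ValueError("model carries no block weights")
    return dict(model.block_weights)


def weighted_vote(
    block_predictions: dict[str, BlockPrediction],
    weights: dict[str, float],
) -> np.ndarray:
    """Fuse per-block votes: each block contributes its weight to its vote.

    The winning class maximizes the summed weight; on a tie, the vote of the
    highest-weight block (earliest block on equal weights) among the tied
    classes wins, falling back to class order.
    """
    if not block_predictions:
        raise ValueError("need at least one block")
    first = next(iter(block_predictions.values()))
    classes = first.classes
    n = len(first.predicted)
    tally = np.zeros((n, len(classes)))
    col = {c: k for k, c in enumerate(classes)}
    for b, pred in block_predictions.items():
        w = float(weights[b])
        for i, c in enumerate(pred.predicted):
            tally[i, col[c]] += w
    order = sorted(block_predictions, key=lambda b: -float(weights[b]))
    out = []
    for i in range(n):
        best = tally[i].max()
        tied = [c for k, c in enumerate(classes) if tally[i, k] == best]
        if len(tied) == 1:
            out.append(tied[0])
            continue
        choice = None
        for b in order:  # highest-weight block whose vote is among the tied
            v = block_predictions[b].predicted[i]
            if v in tied:
                choice = v
                break
        out.append(choice if choice is not None else tied[0])
    return np.asarray(out)


@dataclass
class PerformanceReport:
    classes: list[str]
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    confusion: pd.DataFrame
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "confusion": self.confusion.to_numpy().tolist(),
            "classes": self.classes,
            "undefined": self.undefined,
        }


def performance_metrics(y_true, y_pred, classes: list[str] | None = None) -> PerformanceReport:
    """Accuracy, one-vs-rest precision/recall/F1 and the confusion matrix.

    Ratios with a zero denominator (e.g. a class never predicted) are
    reported as 0 and the affected classes listed in ``undefined``.
    """
    y_true = np.asarray(list(y_true))
    y_pred = np.asarray(list(y_pred))
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.size != y_pred.size:
        raise ValueError("length mismatch")
    if classes is None:
        classes = list(dict.fromkeys(list(y_true) + list(y_pred)))
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0
    )
    undefined = [
        c
        for k, c in enumerate(classes)
        if (y_pred == c).sum() == 0 or (y_true == c).sum() == 0
    ]
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    return PerformanceReport(
        classes=list(classes),
        accuracy=float(np.mean(y_true == y_pred)),
        precision={c: float(prec[k]) for k, c in enumerate(classes)},
        recall={c: float(rec[k]) for k, c in enumerate(classes)},
        f1={c: float(f1[k]) for k, c in enumerate(classes)},
        confusion=pd.DataFrame(cm, index=classes, columns=classes),
        undefined=undefined,
    )


def roc_auc(scores, binary_labels) -> float:
    """One-vs-rest AUC: Mann-Whitney concordance with ties counted 0.5."""
    y = np.asarray(binary_labels)
    if len(np.unique(y)) != 2:
        raise ValueError("need both labels present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def per_class_auc(pred: BlockPrediction, y_true) -> dict[str, float]:
    """AUC per class from the per-class centroid scores (one vs rest)."""
    y_true = np.asarray(list(y_true))
    out = {}
    for k, c in enumerate(pred.classes):
        y = (y_true == c).astype(int)
        if y.min() == y.max():
            continue
        out[c] = roc_auc(pred.scores[:, k], y)
    return out
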