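"""Identification-performance metrics.

Per-frame accuracy, raw and row-normalized confusion matrices, and
one-vs-rest ROC / precision-recall curves with their AUC / average-precision
summaries, plus the stratified 80:20 split protocol used throughout.

Curve sweeps are delegated to scikit-learn's threshold machinery; the
wrappers here pin down the point conventions (ROC anchored at (0,0) and
(1,1), trapezoidal AUC, step-wise AP) and the input validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skmetrics


def stratified_split(labels: Sequence, test_fraction: float = 0.2,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive per-class split of indices.

    Per class the test share is ``max(1, round(test_fraction * class_size))``
    with round-half-up, so every class is represented in the test set.
    A class with a single sample cannot be split and raises.
    """
    labels = np.asarray(labels)
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        if len(members) < 2:
            raise ValueError(f"class {cls!r} has a single sample and cannot be split")
        n_test = max(1, int(np.floor(test_fraction * len(members) + 0.5)))
        n_test = min(n_test, len(members) - 1)
        members = members[rng.permutation(len(members))]
        test_idx.extend(members[:n_test].tolist())
        train_idx.extend(members[n_test:].tolist())
    return np.sort(train_idx), np.sort(test_idx)


def accuracy(predicted: Sequence, actual: Sequence) -> float:
    """Fraction of correct predictions."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if len(predicted) != len(actual):
        raise ValueError("predicted and actual must have equal length")
    if len(predicted) == 0:
        raise ValueError("cannot compute accuracy of an empty prediction set")
    return float((predicted == actual).mean())


@dataclass
class ConfusionMatrix:
    """Square count grid: rows = actual class, columns = predicted class."""

    classes: list
    counts: np.ndarray

    def normalized(self) -> np.ndarray:
        """Row-normalized view; all-zero rows stay zero."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, self.counts / np.maximum(sums, 1), 0.0)
        return out

    def to_frame(self, normalized: bool = False) -> pd.DataFrame:
        data = self.normalized() if normalized else self.counts
        return pd.DataFrame(data, index=self.classes, columns=self.classes)


def confusion(predicted: Sequence, actual: Sequence, classes: Sequence) -> ConfusionMatrix:
    """Tally counts[i, j] = #(actual == classes[i] and predicted == classes[j])."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    classes = list(classes)
    known = set(classes)
    for label in np.concatenate([predicted, actual]):
        if label not in known:
            raise ValueError(f"label {label!r} not in the declared class list")
    counts = _skmetrics.confusion_matrix(actual, predicted, labels=classes)
    return ConfusionMatrix(classes=classes, counts=counts)


@dataclass
class CurveSeries:
    """An ROC or PR curve: ordered points in [0,1]^2 with a scalar summary."""

    points: np.ndarray  # (n, 2)
    kind: str           # "roc" | "pr"
    summary: float      # AUC or AP


def roc_curve(scores_for_class: Sequence[float], is_class_member: Sequence) -> CurveSeries:
    """One-vs-rest ROC from a threshold sweep over the distinct scores.

    Points are (FPR, TPR) with (0, 0) and (1, 1) anchors; the summary is
    the trapezoidal area under the curve.
    """
    scores = np.asarray(scores_for_class, dtype=float)
    members = np.asarray(is_class_member).astype(bool)
    if members.all() or not members.any():
        raise ValueError("ROC needs at least one positive and one negative sample")
    fpr, tpr, _ = _skmetrics.roc_curve(members, scores, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    if not np.array_equal(points[0], [0.0, 0.0]):
        points = np.vstack([[0.0, 0.0], points])
    if not np.array_equal(points[-1], [1.0, 1.0]):
        points = np.vstack([points, [1.0, 1.0]])
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return CurveSeries(points=points, kind="roc", summary=auc)


def pr_curve(scores_for_class: Sequence[float], is_class_member: Sequence) -> CurveSeries:
    """One-vs-rest precision-recall curve with step-wise average precision.

    AP = sum_i (R_i - R_{i-1}) * P_i over thresholds in order of increasing
    recall.
    """
    scores = np.asarray(scores_for_class, dtype=float)
    members = np.asarray(is_class_member).astype(bool)
    if not members.any():
        raise ValueError("PR curve needs at least one positive sample")
    precision, recall, _ = _skmetrics.precision_recall_curve(members, scores)
    # sklearn returns decreasing recall; present points by increasing recall
    points = np.column_stack([recall[::-1], precision[::-1]])
    ap = float(_skmetrics.average_precision_score(members, scores))
    return CurveSeries(points=points, kind="pr", summary=ap)


@dataclass
class EvaluationReport:
    """Accuracy, confusion matrix and per-class one-vs-rest curves."""

    accuracy: float
    confusion: ConfusionMatrix
    per_class_curves: dict  # identity -> {"roc": CurveSeries, "pr": CurveSeries}

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "classes": list(self.confusion.classes),
            "confusion": self.confusion.counts.tolist(),
            "per_class": {
                str(cls): {
                    "auc": curves["roc"].summary if curves["roc"] else None,
                    "ap": curves["pr"].summary if curves["pr"] else None,
                }
                for cls, curves in self.per_class_curves.items()
            },
        }

    def save(self, out_dir: str | Path) -> None:
        """Serialize: report JSON, confusion CSVs, per-class curve CSVs."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(self.to_dict(), indent=2))
        self.confusion.to_frame().to_csv(out_dir / "confusion.csv")
        self.confusion.to_frame(normalized=True).to_csv(out_dir / "confusion_normalized.csv")
        for cls, curves in self.per_class_curves.items():
            for kind in ("roc", "pr"):
                if curves[kind] is None:
                    continue
                cols = ("fpr", "tpr") if kind == "roc" else ("recall", "precision")
                pd.DataFrame(curves[kind].points, columns=cols).to_csv(
                    out_dir / f"{kind}_{cls}.csv", index=False)


def full_report(classifier, test_embeddings: np.ndarray,
                test_labels: Sequence) -> EvaluationReport:
    """Evaluate a fitted classifier on embedded test frames.

    Argmax predictions drive accuracy and the confusion matrix; the
    per-class score columns drive one-vs-rest ROC / PR curves, one pair per
    class present in the test set.
    """
    test_labels = np.asarray(test_labels)
    if len(test_labels) == 0:
        raise ValueError("empty test set")
    if len(np.unique(test_labels)) < 2:
        raise ValueError("test set must cover at least 2 classes")
    predicted, scores = classifier.predict_batch(test_embeddings)
    class_set = list(classifier.class_set)
    all_classes = list(dict.fromkeys(list(class_set) + list(np.unique(test_labels))))
    conf = confusion(predicted, test_labels, all_classes)
    acc = accuracy(predicted, test_labels)
    curves = {}
    for cls in np.unique(test_labels):
        members = test_labels == cls
        col = (scores[:, class_set.index(cls)] if cls in class_set
               else np.zeros(len(test_labels)))
        roc = roc_curve(col, members) if 0 < members.sum() < len(members) else None
        pr = pr_curve(col, members) if members.any() else None
        curves[cls] = {"roc": roc, "pr": pr}
    return EvaluationReport(accuracy=acc, confusion=conf, per_class_curves=curves)


def session_majority_report(classifier, session_embeddings: dict,
                            session_labels: dict) -> float:
    """Optional session-level view: majority vote over each session's frames."""
    correct = 0
    for sid, emb in session_embeddings.items():
        predicted, _ = classifier.predict_batch(np.asarray(emb))
        values, counts = np.unique(predicted, return_counts=True)
        if values[np.argmax(counts)] == session_labels[sid]:
            correct += 1
    if not session_embeddings:
        raise ValueError("no sessions to evaluate")
    return correct / len(session_embeddings)
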