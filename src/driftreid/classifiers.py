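"""Classical classifier bank over embedding vectors.

The identification head is deliberately shallow: a K-nearest-neighbor vote,
a random forest, or a support vector machine (linear or RBF) fitted on the
gallery of stored embeddings.  All classifiers expose calibrated per-class
scores summing to one, usable directly as one-vs-rest curve thresholds.

The KNN vote has an explicit tie rule: among classes tied on vote count, the
class owning the nearest-ranked neighbor wins.  That rule is encoded into
the score vector as an infinitesimal rank bonus, so the reported argmax and
the tie rule always agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from . import evaluation

_KNN_RANK_BONUS = 1e-6  # < 1/k^2 for any supported k: never overturns a vote gap


@dataclass(frozen=True)
class ClassifierSpec:
    """Declarative description of one classifier in the bank."""

    kind: str  # "knn" | "random_forest" | "svm"
    k: int | None = None
    kernel: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("knn", "random_forest", "svm"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.kind == "knn" and (self.k is None or self.k < 1):
            raise ValueError("knn requires a positive k")
        if self.kind == "svm" and self.kernel not in ("linear", "rbf"):
            raise ValueError("svm requires kernel 'linear' or 'rbf'")

    def describe(self) -> str:
        if self.kind == "knn":
            return f"KNN (K = {self.k})"
        if self.kind == "random_forest":
            return "Random forest"
        return f"SVM ({'Linear' if self.kernel == 'linear' else 'RBF'} kernel)"


def default_specs(seed: int = 0) -> list[ClassifierSpec]:
    """The standard six-classifier comparison bank."""
    return [
        ClassifierSpec("knn", k=3),
        ClassifierSpec("knn", k=5),
        ClassifierSpec("knn", k=7),
        ClassifierSpec("random_forest", seed=seed),
        ClassifierSpec("svm", kernel="rbf", seed=seed),
        ClassifierSpec("svm", kernel="linear", seed=seed),
    ]


class FittedClassifier:
    """A fitted bank member: predicts an identity plus per-class scores."""

    def __init__(self, spec: ClassifierSpec, class_set: list, model, train_labels=None):
        self.spec = spec
        self.class_set = class_set
        self._model = model
        self._train_labels = train_labels  # knn only
        self._dim = None

    def _check_embedding(self, embeddings: np.ndarray) -> np.ndarray:
        emb = np.asarray(embeddings, dtype=float)
        if emb.ndim == 1:
            emb = emb[None]
        if self._dim is not None and emb.shape[1] != self._dim:
            raise ValueError(f"expected {self._dim}-d embeddings, got {emb.shape[1]}-d")
        return emb

    def predict_batch(self, embeddings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predict identities and an (n, n_classes) score matrix (rows sum to 1)."""
        emb = self._check_embedding(embeddings)
        if self.spec.kind == "knn":
            scores = self._knn_scores(emb)
        else:
            proba = self._model.predict_proba(emb)
            scores = np.zeros((len(emb), len(self.class_set)))
            for j, cls in enumerate(self._model.classes_):
                scores[:, self.class_set.index(cls)] = proba[:, j]
        predicted = np.asarray([self.class_set[j] for j in scores.argmax(axis=1)])
        return predicted, scores

    def predict(self, embedding: np.ndarray) -> tuple[object, np.ndarray]:
        predicted, scores = self.predict_batch(embedding)
        return predicted[0], scores[0]

    def _knn_scores(self, emb: np.ndarray) -> np.ndarray:
        k = self.spec.k
        _, neighbor_idx = self._model.kneighbors(emb, n_neighbors=k)
        scores = np.zeros((len(emb), len(self.class_set)))
        class_pos = {cls: j for j, cls in enumerate(self.class_set)}
        for i, row in enumerate(neighbor_idx):
            neighbor_labels = self._train_labels[row]
            for rank, label in enumerate(neighbor_labels):
                j = class_pos[label]
                scores[i, j] += 1.0 / k
                # rank bonus implements the tie rule (nearest neighbor wins),
                # granted once per class at its best rank
                if not any(class_pos[l] == j for l in neighbor_labels[:rank]):
                    scores[i, j] += _KNN_RANK_BONUS * (k - rank) / k
        return scores / scores.sum(axis=1, keepdims=True)


def fit(spec: ClassifierSpec, embeddings: np.ndarray, labels: Sequence) -> FittedClassifier:
    """Fit one bank member on a labeled embedding gallery."""
    emb = np.asarray(embeddings, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("fitting requires at least 2 classes")
    if spec.kind == "knn":
        if len(emb) < spec.k:
            raise ValueError(f"knn with k={spec.k} needs at least {spec.k} training points")
        model = NearestNeighbors(n_neighbors=spec.k).fit(emb)
        fitted = FittedClassifier(spec, classes, model, train_labels=labels)
    elif spec.kind == "random_forest":
        model = RandomForestClassifier(n_estimators=100, random_state=spec.seed)
        model.fit(emb, labels)
        fitted = FittedClassifier(spec, classes, model)
    else:
        gamma = "scale" if spec.kernel == "rbf" else "auto"
        model = SVC(kernel=spec.kernel, C=1.0, gamma=gamma, probability=True,
                    random_state=spec.seed)
        model.fit(emb, labels)
        fitted = FittedClassifier(spec, classes, model)
    fitted._dim = emb.shape[1]
    return fitted


def compare_classifiers(specs: Sequence[ClassifierSpec],
                        train_set: tuple[np.ndarray, Sequence],
                        test_set: tuple[np.ndarray, Sequence]) -> pd.DataFrame:
    """Fit every spec on the train gallery; tabulate test accuracy.

    Rows are sorted by accuracy descending, ties resolved by spec order.
    """
    train_emb, train_labels = train_set
    test_emb, test_labels = test_set
    if len(np.asarray(test_labels)) == 0:
        raise ValueError("empty test set")
    rows = []
    for order, spec in enumerate(specs):
        fitted = fit(spec, train_emb, train_labels)
        predicted, _ = fitted.predict_batch(test_emb)
        rows.append({
            "classifier": spec.describe(),
            "parameters": _param_string(spec),
            "accuracy": evaluation.accuracy(predicted, test_labels),
            "_order": order,
        })
    table = pd.DataFrame(rows).sort_values(
        ["accuracy", "_order"], ascending=[False, True], kind="stable")
    return table.drop(columns="_order").reset_index(drop=True)


def _param_string(spec: ClassifierSpec) -> str:
    if spec.kind == "knn":
        return f"k={spec.k}"
    if spec.kind == "random_forest":
        return f"n_estimators=100, seed={spec.seed}"
    return f"kernel={spec.kernel}, C=1.0"
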