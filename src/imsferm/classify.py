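"""HCA and supervised classification on decomposition scores.

Samples are described by their PCA or NNMF scores (a handful of features per
sample); class structure is explored by Ward-linkage hierarchical clustering
and predicted by four supervised models:

* LDA  - pooled-covariance linear discriminant analysis,
* kNN  - Euclidean 5-nearest-neighbour majority vote; a tied vote is re-run
         with k reduced by one until resolved (final fallback: the single
         nearest neighbour),
* SVM  - linear-kernel one-vs-one support vector machine (cost 1) on
         unit-variance standardized features,
* PLS-DA - partial least squares against a one-hot class response, predicted
         class = argmax of the fitted indicators.

Model quality is reported the way chemometric studies print it: the
cross-validation error rate as a one-decimal percentage of misclassified
training samples, and the held-out prediction accuracy as an integer
percentage, both rounded half away from zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.cluster.hierarchy import to_tree
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "SplitPlan",
    "Dendrogram",
    "ClassifierReport",
    "stratified_split",
    "hca",
    "train_classifier",
    "cross_validate",
    "evaluate_test",
    "format_error_rate",
    "format_accuracy",
    "CLASSIFIER_KINDS",
]

logger = logging.getLogger(__name__)

CLASSIFIER_KINDS = ("lda", "knn5", "svm", "plsda")


def _round_half_up(x: Decimal, quantum: str) -> float:
    return float(x.quantize(Decimal(quantum), rounding=ROUND_HALF_UP))


def format_error_rate(misclassified: int, total: int) -> float:
    """CV error as a one-decimal percent, rounded half away from zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= misclassified <= total:
        raise ValueError("misclassified must be within [0, total]")
    return _round_half_up(Decimal(100 * misclassified) / Decimal(total), "0.1")


def format_accuracy(correct: int, total: int) -> int:
    """Prediction accuracy as an integer percent, rounded half away from zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= correct <= total:
        raise ValueError("correct must be within [0, total]")
    return int(_round_half_up(Decimal(100 * correct) / Decimal(total), "1"))


@dataclass
class SplitPlan:
    """Stratified train/test index split."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    fraction: float
    per_class_train: dict[str, int]


def stratified_split(
    labels: list[str], fraction: float = 0.8, seed: int = 0
) -> SplitPlan:
    """Per-class 80:20 split with half-up rounding of the train count.

    Each class contributes ``round(fraction * n_c)`` (half rounded up)
    training samples, chosen by a seeded shuffle within the class.
    """
    labels_arr = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train: list[int] = []
    test: list[int] = []
    per_class: dict[str, int] = {}
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(labels_arr == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        n_train = int(math.floor(fraction * idx.size + 0.5))
        n_train = min(n_train, idx.size)
        shuffled = rng.permutation(idx)
        train.extend(shuffled[:n_train].tolist())
        test.extend(shuffled[n_train:].tolist())
        per_class[cls] = n_train
    if not test:
        raise ValueError("split produced an empty test set")
    return SplitPlan(
        train_indices=np.sort(np.asarray(train)),
        test_indices=np.sort(np.asarray(test)),
        fraction=fraction,
        per_class_train=per_class,
    )


@dataclass
class Dendrogram:
    """Agglomerative merge sequence (scipy linkage matrix) plus leaf labels."""

    merges: np.ndarray  # (n-1) x 4 linkage matrix
    leaf_labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        """Newick text with branch lengths derived from merge heights."""
        tree = to_tree(self.merges)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaf_labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def hca(
    scores: np.ndarray,
    metric: str = "euclidean",
    method: str = "ward",
    labels: list[str] | None = None,
) -> Dendrogram:
    """Hierarchical cluster analysis (default: Euclidean distance, Ward).

    Under Ward linkage the first merge of two singleton points occurs at
    their plain Euclidean distance (scipy's Ward convention).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2:
        raise ValueError("hca requires a 2-D score matrix with >= 2 rows")
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN")
    merges = _scipy_linkage(scores, method=method, metric=metric)
    if labels is None:
        labels = [str(i) for i in range(scores.shape[0])]
    return Dendrogram(merges=merges, leaf_labels=list(labels))


class KNNClassifier:
    """Euclidean k-nearest-neighbour vote with a decrementing-k tie-break."""

    def __init__(self, k: int = 5):
        self.k = k
        self._X: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KNNClassifier":
        self._X = np.asarray(X, float)
        self._y = np.asarray(y)
        return self

    def _predict_one(self, x: np.ndarray) -> object:
        d = np.linalg.norm(self._X - x, axis=1)
        order = np.argsort(d, kind="stable")
        k = min(self.k, order.size)
        while k >= 1:
            votes = self._y[order[:k]]
            classes, counts = np.unique(votes, return_counts=True)
            winners = classes[counts == counts.max()]
            if winners.size == 1 or k == 1:
                if winners.size == 1:
                    return winners[0]
                # still tied at k=1 cannot happen; nearest single neighbour
                return self._y[order[0]]
            k -= 1
        return self._y[order[0]]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return np.asarray([self._predict_one(x) for x in X])


class PLSDAClassifier:
    """PLS regression on one-hot class indicators; class = argmax."""

    def __init__(self, n_components: int = 2):
        self.n_components = n_components
        self.classes_: np.ndarray | None = None
        self._pls: PLSRegression | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PLSDAClassifier":
        X = np.asarray(X, float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        onehot = (y[:, None] == self.classes_[None, :]).astype(float)
        n_comp = min(self.n_components, X.shape[1], X.shape[0] - 1)
        self._pls = PLSRegression(n_components=n_comp, scale=False)
        self._pls.fit(X, onehot)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        indicators = self._pls.predict(np.atleast_2d(np.asarray(X, float)))
        return self.classes_[np.argmax(indicators, axis=1)]


def train_classifier(
    kind: str, features: np.ndarray, labels: list[str] | np.ndarray, **params
):
    """Fit one of the four supervised models on training features."""
    features = np.asarray(features, float)
    labels = np.asarray(labels)
    if not np.isfinite(features).all():
        raise ValueError("features must be finite")
    n_classes = np.unique(labels).size
    if features.shape[0] < n_classes:
        raise ValueError("fewer training rows than classes")
    if kind == "lda":
        model = LinearDiscriminantAnalysis(**params)
    elif kind in ("knn", "knn5"):
        model = KNNClassifier(k=params.get("k", 5))
    elif kind == "svm":
        model = make_pipeline(
            StandardScaler(), SVC(kernel="linear", C=params.get("C", 1.0))
        )
    elif kind == "plsda":
        model = PLSDAClassifier(
            n_components=params.get("n_components", max(2, n_classes - 1))
        )
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    return model.fit(features, labels)


def _stratified_folds(
    labels: np.ndarray, folds: int, seed: int
) -> np.ndarray:
    """Seeded stratified fold assignment; every sample lands in one fold."""
    assignment = np.full(labels.size, -1, dtype=int)
    rng = np.random.default_rng(seed)
    offset = 0
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        if idx.size < folds:
            logger.warning(
                "class %r has %d members < %d folds; stratification relaxed",
                cls, idx.size, folds,
            )
        shuffled = rng.permutation(idx)
        assignment[shuffled] = (np.arange(idx.size) + offset) % folds
        offset += idx.size
    assert (assignment >= 0).all()
    return assignment


@dataclass
class ClassifierReport:
    """A study-style result row: CV error and held-out accuracy."""

    method: str
    feature_source: str
    n_components: int
    cv_folds: int
    cv_misclassified: int
    cv_total: int
    cv_error_pct: float
    test_correct: int
    test_total: int
    test_accuracy_pct: int

    def __post_init__(self) -> None:
        assert self.cv_error_pct == format_error_rate(
            self.cv_misclassified, self.cv_total
        )
        assert self.test_accuracy_pct == format_accuracy(
            self.test_correct, self.test_total
        )

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def cross_validate(
    kind: str,
    features: np.ndarray,
    labels: list[str] | np.ndarray,
    folds: int = 10,
    seed: int = 0,
    **params,
) -> tuple[int, dict]:
    """Stratified k-fold CV; each sample is predicted exactly once.

    Returns the misclassified count and a dict of report fields (counts and
    the formatted one-decimal error rate).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    features = np.asarray(features, float)
    labels = np.asarray(labels)
    assignment = _stratified_folds(labels, folds, seed)
    predictions = np.empty(labels.size, dtype=labels.dtype)
    seen = np.zeros(labels.size, dtype=bool)
    for fold in range(folds):
        test_mask = assignment == fold
        if not test_mask.any():
            continue
        model = train_classifier(
            kind, features[~test_mask], labels[~test_mask], **params
        )
        predictions[test_mask] = model.predict(features[test_mask])
        assert not seen[test_mask].any(), "fold leakage"
        seen[test_mask] = True
    assert seen.all(), "every sample must be predicted exactly once"
    misclassified = int((predictions != labels).sum())
    return misclassified, {
        "cv_folds": folds,
        "cv_misclassified": misclassified,
        "cv_total": int(labels.size),
        "cv_error_pct": format_error_rate(misclassified, labels.size),
    }


def evaluate_test(
    model, features: np.ndarray, labels: list[str] | np.ndarray
) -> dict:
    """Held-out evaluation: correct count and integer-percent accuracy."""
    labels = np.asarray(labels)
    predictions = model.predict(np.asarray(features, float))
    correct = int((predictions == labels).sum())
    return {
        "test_correct": correct,
        "test_total": int(labels.size),
        "test_accuracy_pct": format_accuracy(correct, labels.size),
    }
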