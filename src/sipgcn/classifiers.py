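"""Final SIP prediction: random forest, plus KNN and ELM ablation classifiers.

The random forest follows the bagging/voting strategy explicitly: (a) draw
bootstrap sub-datasets with replacement, (b) fit one decision tree per
sub-dataset, (c) combine tree outputs by majority vote.  Tree induction is
delegated to scikit-learn's CART trees; the bootstrap and voting logic is
implemented here.  Scores are in [0, 1] with higher meaning more likely SIP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)


def majority_vote(votes: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Combine per-tree binary votes (n_trees x n_samples) into predictions.

    The score is the fraction of trees voting positive; the prediction is 1
    when the score strictly exceeds 1/2, so exact ties go to the
    (majority) negative class.
    """
    votes = np.asarray(votes, dtype=float)
    scores = votes.mean(axis=0)
    return (scores > 0.5).astype(int), scores


@dataclass
class TrainedClassifier:
    """A fitted classifier with deterministic predict/score methods."""

    kind: str
    seed: int
    trees: Optional[List[DecisionTreeClassifier]] = None
    classes: Optional[np.ndarray] = None

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        if self.kind != "rf":
            raise NotImplementedError(f"score_samples for kind {self.kind!r}")
        votes = np.vstack([self._tree_votes(t, X) for t in self.trees])
        return votes.mean(axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        votes = np.vstack([self._tree_votes(t, X) for t in self.trees])
        return majority_vote(votes)[0]

    @staticmethod
    def _tree_votes(tree: DecisionTreeClassifier, X: np.ndarray) -> np.ndarray:
        return tree.predict(X).astype(int)


def rf_fit(
    features: np.ndarray,
    labels: np.ndarray,
    n_trees: int = 100,
    seed: int = 0,
    *,
    bootstrap: bool = True,
    max_features: str | int | float | None = "sqrt",
) -> TrainedClassifier:
    """Fit a random forest by bootstrap bagging with majority voting.

    Each of the ``n_trees`` trees is trained on a resample of size n drawn
    with replacement (``bootstrap=False`` disables resampling, a test
    hook); per-split feature subsampling defaults to sqrt(d) and tree
    depth is unlimited.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] < 2:
        raise ValueError("need at least two training samples")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    trees: List[DecisionTreeClassifier] = []
    for _ in range(n_trees):
        idx = rng.integers(0, n, size=n) if bootstrap else np.arange(n)
        tree = DecisionTreeClassifier(
            max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
    return TrainedClassifier(kind="rf", seed=seed, trees=trees, classes=np.unique(y))


def knn_predict(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    k: int = 5,
) -> Tuple[np.ndarray, np.ndarray]:
    """Euclidean k-nearest-neighbour scores and predictions.

    The score is the fraction of positive labels among the k nearest
    training points (stable index order breaks distance ties); the
    prediction is 1 when the score strictly exceeds 1/2.
    Returns ``(scores, predictions)``.
    """
    Xtr = np.asarray(train_features, dtype=float)
    ytr = np.asarray(train_labels, dtype=int)
    Xte = np.atleast_2d(np.asarray(test_features, dtype=float))
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > Xtr.shape[0]:
        raise ValueError(f"k={k} exceeds the {Xtr.shape[0]} training samples")
    dists = cdist(Xte, Xtr)
    order = np.argsort(dists, axis=1, kind="stable")[:, :k]
    scores = ytr[order].mean(axis=1)
    return scores, (scores > 0.5).astype(int)


def elm_fit_predict(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    hidden: int = 256,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Extreme learning machine: random sigmoid hidden layer, least-squares output.

    Input weights and biases are drawn once from the seeded generator and
    never trained; output weights solve the least-squares problem against
    +/-1 targets by pseudo-inverse.  The returned score is the logistic of
    the real-valued output; the prediction is 1 when the output is
    positive.  Returns ``(scores, predictions)``.
    """
    Xtr = np.asarray(train_features, dtype=float)
    ytr = np.asarray(train_labels, dtype=int)
    Xte = np.atleast_2d(np.asarray(test_features, dtype=float))
    if hidden < 1:
        raise ValueError("hidden must be >= 1")
    rng = np.random.default_rng(seed)
    d = Xtr.shape[1]
    W = rng.normal(size=(d, hidden))
    b = rng.normal(size=hidden)

    def hidden_layer(X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(X @ W + b)))

    H = hidden_layer(Xtr)
    targets = 2.0 * ytr - 1.0
    if np.ptp(H, axis=0).max() < 1e-12:
        logger.warning("degenerate ELM hidden outputs; falling back to ridge solve")
        beta = np.linalg.solve(H.T @ H + 1e-6 * np.eye(hidden), H.T @ targets)
    else:
        beta, *_ = np.linalg.lstsq(H, targets, rcond=None)
    out = hidden_layer(Xte) @ beta
    scores = 1.0 / (1.0 + np.exp(-out))
    return scores, (out > 0).astype(int)


def fit_predict(
    kind: str,
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    *,
    seed: int = 0,
    n_trees: int = 100,
    knn_k: int = 5,
    elm_hidden: int = 256,
) -> Tuple[np.ndarray, np.ndarray]:
    """Uniform train-then-score entry point over the three classifier kinds.

    Returns ``(scores, predictions)`` on the test features.
    """
    if kind == "rf":
        clf = rf_fit(train_features, train_labels, n_trees=n_trees, seed=seed)
        scores = clf.score_samples(test_features)
        return scores, (scores > 0.5).astype(int)
    if kind == "knn":
        return knn_predict(train_features, train_labels, test_features, k=knn_k)
    if kind == "elm":
        return elm_fit_predict(
            train_features, train_labels, test_features, hidden=elm_hidden, seed=seed
        )
    raise ValueError(f"unknown classifier kind {kind!r}")
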