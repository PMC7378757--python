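"""Classifier suite: kNN, linear/RBF SVM, LDA, decision tree, and
one-versus-one ECOC multiclass wrapping for the SVMs.

scikit-learn provides the fitted estimators; the pieces with contracts the
library does not guarantee are implemented here — kNN neighbour and vote
tie-breaking, and ECOC decoding (pairwise majority vote, ties resolved by
the largest sum of signed decision margins, then by class order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Any

import joblib
import numpy as np
from scipy.spatial.distance import cdist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "EcocEnsemble",
    "MODEL_FAMILIES",
    "train",
    "train_ecoc",
    "predict",
    "save_model",
    "load_model",
]

MODEL_FAMILIES = ("knn", "linear_svm", "rbf_svm", "lda", "decision_tree")
_KNN_GRID = (1, 3, 5, 7)
_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one classifier.

    ``C`` is the SVM regularisation constant; ``gamma`` the RBF kernel
    width (``"auto"`` = 1/n_features, appropriate on standardised inputs).
    LDA and the decision tree use empirical class priors, which is what
    fitting on raw label frequencies yields.
    """

    family: str
    k: int = 5
    C: float = 1.0
    gamma: float | str = "auto"
    criterion: str = "gini"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.family == "knn" and self.k not in _KNN_GRID:
            raise ValueError(f"k must be one of {_KNN_GRID}")
        if self.C <= 0:
            raise ValueError("C must be positive")


class _KNeighbours:
    """Euclidean kNN with deterministic tie-breaking.

    Neighbour ties at the k-th distance are broken by lowest training
    sample index; vote ties are broken by the class of the single nearest
    neighbour.
    """

    def __init__(self, k: int) -> None:
        self.k = k

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_KNeighbours":
        self._X = X
        self._y = y
        self.classes_ = np.unique(y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        dists = cdist(np.asarray(X, dtype=float), self._X)
        n_train = self._X.shape[0]
        order = np.lexsort((np.tile(np.arange(n_train), (dists.shape[0], 1)), dists), axis=1)
        nearest = order[:, : min(self.k, n_train)]
        out = np.empty(X.shape[0], dtype=self._y.dtype)
        for i, idx in enumerate(nearest):
            labels, counts = np.unique(self._y[idx], return_counts=True)
            winners = labels[counts == counts.max()]
            if len(winners) == 1:
                out[i] = winners[0]
            else:
                # vote tie: fall back to the single nearest neighbour's class
                out[i] = self._y[idx[0]]
        return out


@dataclass(frozen=True)
class TrainedModel:
    """A fitted classifier together with its spec and training label set."""

    spec: ModelSpec
    estimator: Any = field(repr=False)
    classes: tuple = ()


@dataclass(frozen=True)
class EcocEnsemble:
    """One-versus-one ECOC ensemble of binary SVMs.

    Holds K(K-1)/2 base models, one per unordered class pair, each trained
    only on that pair's samples.
    """

    base_spec: ModelSpec
    pair_models: tuple[tuple[tuple[Any, Any], Any], ...] = field(repr=False)
    classes: tuple = ()


def _build_estimator(spec: ModelSpec):
    if spec.family == "knn":
        return _KNeighbours(spec.k)
    if spec.family == "linear_svm":
        return SVC(kernel="linear", C=spec.C)
    if spec.family == "rbf_svm":
        return SVC(kernel="rbf", C=spec.C, gamma=spec.gamma)
    if spec.family == "lda":
        # SVD solver: tolerance-based pseudoinverse handles the collinear
        # feature pairs this feature set produces (e.g. std vs rms on
        # near-zero-mean channels); priors default to class frequencies.
        return LinearDiscriminantAnalysis(solver="svd")
    return DecisionTreeClassifier(
        criterion=spec.criterion, min_samples_leaf=1, random_state=spec.seed
    )


def _validate_training_data(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("training features contain non-finite values")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    return X, y


def train(spec: ModelSpec, X: np.ndarray, y: np.ndarray) -> TrainedModel:
    """Fit one classifier on a feature matrix and label vector."""
    X, y = _validate_training_data(X, y)
    estimator = _build_estimator(spec).fit(X, y)
    return TrainedModel(spec=spec, estimator=estimator, classes=tuple(np.unique(y)))


def train_ecoc(base_spec: ModelSpec, X: np.ndarray, y: np.ndarray) -> EcocEnsemble:
    """Fit a one-versus-one ECOC ensemble of binary SVMs.

    One base model per unordered class pair (K(K-1)/2 in total), each
    trained only on the samples of its two classes.
    """
    if base_spec.family not in ("linear_svm", "rbf_svm"):
        raise ValueError("ECOC base models must be linear_svm or rbf_svm")
    X, y = _validate_training_data(X, y)
    classes = tuple(np.unique(y))
    pair_models = []
    for a, b in combinations(classes, 2):
        mask = (y == a) | (y == b)
        est = _build_estimator(base_spec).fit(X[mask], y[mask])
        pair_models.append(((a, b), est))
    return EcocEnsemble(base_spec=base_spec, pair_models=tuple(pair_models), classes=classes)


def _predict_ecoc(model: EcocEnsemble, X: np.ndarray) -> np.ndarray:
    classes = list(model.classes)
    index = {c: i for i, c in enumerate(classes)}
    n = X.shape[0]
    votes = np.zeros((n, len(classes)))
    margins = np.zeros((n, len(classes)))
    for (a, b), est in model.pair_models:
        d = est.decision_function(X)  # positive margin favours est.classes_[1]
        lo, hi = est.classes_
        winner = np.where(d > 0, index[hi], index[lo])
        votes[np.arange(n), winner] += 1
        margins[:, index[hi]] += d
        margins[:, index[lo]] -= d
    out = np.empty(n, dtype=object)
    for i in range(n):
        top = votes[i].max()
        tied = np.flatnonzero(votes[i] == top)
        if len(tied) > 1:
            best = margins[i, tied].max()
            tied = tied[margins[i, tied] == best]  # then smallest class index
        out[i] = classes[tied[0]]
    return out


def predict(model: TrainedModel | EcocEnsemble, X: np.ndarray) -> np.ndarray:
    """Predict one label per row; only labels seen in training can occur."""
    X = np.asarray(X, dtype=float)
    if isinstance(model, EcocEnsemble):
        return _predict_ecoc(model, X)
    return model.estimator.predict(X)


def save_model(model: TrainedModel | EcocEnsemble, path) -> None:
    """Persist a trained model as a versioned joblib container."""
    kind = "ecoc" if isinstance(model, EcocEnsemble) else "single"
    joblib.dump({"format_version": _MODEL_FORMAT_VERSION, "kind": kind, "model": model}, path)


def load_model(path) -> TrainedModel | EcocEnsemble:
    """Load a model written by :func:`save_model`."""
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model container version {version!r}")
    return payload["model"]
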