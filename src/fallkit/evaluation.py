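"""Leave-one-subject-out evaluation, metrics, and decision-tree feature
selection.

Each fold holds out every sample of one subject; features are z-scored with
training-fold statistics only.  Reported accuracy and class-averaged
(macro) F1 are arithmetic means over folds, while confusion matrices are
pooled counts over folds.  Feature selection averages the decision tree's
per-fold predictor importance — the summed risk reduction of all splits on
a predictor divided by the number of branch nodes — and keeps features
whose mean importance strictly exceeds a threshold (default 0.0002).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import FeatureVector
from .models import EcocEnsemble, ModelSpec, TrainedModel, predict, train, train_ecoc
from .simulate import FALL_LABEL

__all__ = [
    "FeatureDataset",
    "FoldSplit",
    "ConfusionMatrix",
    "EvaluationReport",
    "ImportanceTable",
    "REFERENCE_13_FEATURES",
    "NO_FALL_LABEL",
    "to_binary_labels",
    "loso_folds",
    "standardize",
    "metrics",
    "run_loso",
    "dt_importance",
    "loso_dt_importance",
    "select_features",
]

logger = logging.getLogger(__name__)

NO_FALL_LABEL = "No Fall"

#: Reference 13-feature subset for the reduced-feature configuration:
#: the result of the importance-selection procedure on the full study —
#: mostly x/z-axis moments, one y-axis autocorrelation position, two
#: x-axis spectral peak amplitudes and two z-axis band powers.
REFERENCE_13_FEATURES: tuple[str, ...] = (
    "mean.x",
    "mean.z",
    "rms.x",
    "rms.z",
    "std.z",
    "skewness.z",
    "kurtosis.z",
    "acf_peak2_pos.y",
    "psd_peak1_amp.x",
    "psd_peak2_amp.x",
    "psd_peak3_pos.z",
    "bandpower_0.5_5.z",
    "bandpower_5_10.z",
)


@dataclass(frozen=True)
class FeatureDataset:
    """Feature matrix with labels, subject ids and feature names."""

    X: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    subjects: np.ndarray = field(repr=False)
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        labels = np.asarray(self.labels)
        subjects = np.asarray(self.subjects)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError("X must be 2-D with one column per feature name")
        if not (X.shape[0] == labels.shape[0] == subjects.shape[0]):
            raise ValueError("X, labels and subjects must have equal length")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "subjects", subjects)

    @classmethod
    def from_feature_vectors(cls, vectors: list[FeatureVector]) -> "FeatureDataset":
        if not vectors:
            raise ValueError("no feature vectors given")
        names = vectors[0].names
        if any(v.names != names for v in vectors):
            raise ValueError("feature vectors have inconsistent name order")
        return cls(
            X=np.stack([v.values for v in vectors]),
            labels=np.array([v.label for v in vectors]),
            subjects=np.array([v.subject_id for v in vectors]),
            feature_names=tuple(names),
        )

    def restrict(self, feature_subset: list[str] | tuple[str, ...]) -> "FeatureDataset":
        """Dataset restricted to the named features, in the given order."""
        missing = [f for f in feature_subset if f not in self.feature_names]
        if missing:
            raise KeyError(f"unknown feature names: {missing}")
        idx = [self.feature_names.index(f) for f in feature_subset]
        return FeatureDataset(
            X=self.X[:, idx],
            labels=self.labels,
            subjects=self.subjects,
            feature_names=tuple(feature_subset),
        )

    def with_binary_labels(self) -> "FeatureDataset":
        return replace(self, labels=to_binary_labels(self.labels))


def to_binary_labels(labels: np.ndarray) -> np.ndarray:
    """Collapse the 7-class labels onto the Fall / No Fall dichotomy."""
    labels = np.asarray(labels)
    return np.where(labels == FALL_LABEL, FALL_LABEL, NO_FALL_LABEL)


@dataclass(frozen=True)
class FoldSplit:
    """One leave-one-subject-out fold."""

    subject_id: str
    train_idx: np.ndarray = field(repr=False)
    test_idx: np.ndarray = field(repr=False)


def loso_folds(subjects: np.ndarray) -> list[FoldSplit]:
    """One fold per subject (sorted order); the fold tests on that subject only."""
    subjects = np.asarray(subjects)
    unique = sorted(set(subjects.tolist()))
    if len(unique) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    folds = []
    for sid in unique:
        test = np.flatnonzero(subjects == sid)
        train = np.flatnonzero(subjects != sid)
        folds.append(FoldSplit(subject_id=sid, train_idx=train, test_idx=test))
    return folds


def standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score both sets with the training set's mean and population SD.

    Features constant in the training set map to 0 in both sets.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.shape[0] == 0:
        raise ValueError("training set must be non-empty")
    mean = train.mean(axis=0)
    sd = train.std(axis=0)  # population (ddof=0)
    safe = np.where(sd == 0, 1.0, sd)
    train_z = (train - mean) / safe
    test_z = (test - mean) / safe
    zero = sd == 0
    train_z[:, zero] = 0.0
    test_z[:, zero] = 0.0
    return train_z, test_z


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts[true][predicted] over a fixed label order."""

    labels: tuple
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        k = len(self.labels)
        if counts.shape != (k, k) or np.any(counts < 0):
            raise ValueError("counts must be a non-negative (k, k) matrix")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_predictions(cls, y_true, y_pred, labels) -> "ConfusionMatrix":
        labels = tuple(labels)
        index = {label: i for i, label in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(labels=labels, counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("confusion matrices have different label sets")
        return ConfusionMatrix(labels=self.labels, counts=self.counts + other.counts)


def metrics(confusion: ConfusionMatrix) -> tuple[float, float]:
    """(accuracy, class-averaged F1) of a confusion matrix, as fractions.

    Per-class F1 is the harmonic mean of precision and recall, defined as
    0 when precision + recall is 0; classes with no true instances and no
    predictions are skipped (logged), since neither precision nor recall
    is defined for them.
    """
    counts = confusion.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = float(np.trace(counts) / total)
    f1s = []
    for i, label in enumerate(confusion.labels):
        tp = counts[i, i]
        fn = counts[i].sum() - tp
        fp = counts[:, i].sum() - tp
        if tp + fn + fp == 0:
            logger.warning("class %r absent from truth and predictions; F1 skipped", label)
            continue
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom > 0 else 0.0)
    return accuracy, float(np.mean(f1s))


@dataclass(frozen=True)
class EvaluationReport:
    """Per-fold and aggregate LOSO metrics plus the pooled confusion matrix.

    ``accuracy`` and ``macro_f1`` are arithmetic means of the per-fold
    values (fractions in [0, 1]); the confusion matrix pools counts over
    folds, so its total equals the dataset size.
    """

    model_spec: ModelSpec
    fold_subjects: tuple[str, ...]
    fold_accuracy: tuple[float, ...]
    fold_macro_f1: tuple[float, ...]
    confusion: ConfusionMatrix

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def macro_f1(self) -> float:
        return float(np.mean(self.fold_macro_f1))

    def summary(self) -> str:
        return (
            f"{self.model_spec.family}: accuracy {100 * self.accuracy:.2f}%, "
            f"class-averaged F1 {100 * self.macro_f1:.2f}% "
            f"({len(self.fold_subjects)} folds, {self.confusion.total} samples)"
        )


def _fit_for_fold(spec: ModelSpec, X: np.ndarray, y: np.ndarray):
    if spec.family in ("linear_svm", "rbf_svm") and len(np.unique(y)) > 2:
        return train_ecoc(spec, X, y)
    return train(spec, X, y)


def run_loso(
    dataset: FeatureDataset,
    model_spec: ModelSpec,
    feature_subset: list[str] | tuple[str, ...] | None = None,
) -> EvaluationReport:
    """Leave-one-subject-out evaluation of one classifier.

    Per fold: restrict to ``feature_subset`` (if given), z-score with
    training statistics, fit, predict the held-out subject, and score.
    Multiclass SVM specs are automatically wrapped in a one-versus-one
    ECOC ensemble.
    """
    if feature_subset is not None:
        dataset = dataset.restrict(feature_subset)
    labels = tuple(sorted(set(dataset.labels.tolist())))
    folds = loso_folds(dataset.subjects)
    accs, f1s, subjects = [], [], []
    pooled: ConfusionMatrix | None = None
    for fold in folds:
        train_X, test_X = standardize(dataset.X[fold.train_idx], dataset.X[fold.test_idx])
        model = _fit_for_fold(model_spec, train_X, dataset.labels[fold.train_idx])
        y_pred = predict(model, test_X)
        cm = ConfusionMatrix.from_predictions(
            dataset.labels[fold.test_idx], y_pred, labels
        )
        acc, f1 = metrics(cm)
        accs.append(acc)
        f1s.append(f1)
        subjects.append(fold.subject_id)
        pooled = cm if pooled is None else pooled + cm
    return EvaluationReport(
        model_spec=model_spec,
        fold_subjects=tuple(subjects),
        fold_accuracy=tuple(accs),
        fold_macro_f1=tuple(f1s),
        confusion=pooled,
    )


def dt_importance(tree: TrainedModel) -> np.ndarray:
    """Per-feature importance of a fitted decision tree.

    For each branch (internal) node splitting on feature j the risk drop
    ``risk(node) - risk(left) - risk(right)`` is accrued to j, where
    ``risk = node probability x node impurity``; the accrued sums are then
    divided by the number of branch nodes.  Features never split on score 0.
    """
    if isinstance(tree, EcocEnsemble) or tree.spec.family != "decision_tree":
        raise TypeError("dt_importance requires a fitted decision tree model")
    t = tree.estimator.tree_
    n_total = t.weighted_n_node_samples[0]
    importances = np.zeros(tree.estimator.n_features_in_)
    branch_nodes = 0
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:  # leaf
            continue
        branch_nodes += 1
        risk = lambda i: (t.weighted_n_node_samples[i] / n_total) * t.impurity[i]
        importances[t.feature[node]] += risk(node) - risk(left) - risk(right)
    if branch_nodes == 0:
        return importances
    return importances / branch_nodes


@dataclass(frozen=True)
class ImportanceTable:
    """Per-fold decision-tree importances (folds x features) and their mean."""

    per_fold: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if (self.per_fold.values < 0).any():
            raise ValueError("importances must be non-negative")

    @property
    def mean_importance(self) -> pd.Series:
        return self.per_fold.mean(axis=0)


def loso_dt_importance(
    dataset: FeatureDataset, model_spec: ModelSpec | None = None
) -> ImportanceTable:
    """Decision-tree importances per LOSO fold.

    Mirrors :func:`run_loso`'s per-fold preparation (training-fold
    standardisation) and records the tree importance of every feature at
    each fold.
    """
    if model_spec is None:
        model_spec = ModelSpec(family="decision_tree")
    if model_spec.family != "decision_tree":
        raise ValueError("importance selection uses the decision-tree classifier")
    folds = loso_folds(dataset.subjects)
    rows = {}
    for fold in folds:
        train_X, _ = standardize(dataset.X[fold.train_idx], dataset.X[fold.test_idx])
        model = train(model_spec, train_X, dataset.labels[fold.train_idx])
        rows[fold.subject_id] = dt_importance(model)
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(dataset.feature_names))
    return ImportanceTable(per_fold=frame)


def select_features(importances: ImportanceTable, threshold: float = 0.0002) -> list[str]:
    """Features whose mean importance across folds strictly exceeds the threshold."""
    mean = importances.mean_importance
    return [name for name in mean.index if mean[name] > threshold]
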