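import numpy as np
import pandas as pd
import pytest

import fallkit as fk
from fallkit.evaluation import ConfusionMatrix, ImportanceTable, NO_FALL_LABEL
from fallkit.models import ModelSpec


class TestLosoFolds:
    def test_folds_partition_the_dataset(self):
        subjects = np.repeat([f"S{i}" for i in range(5)], 7)
        folds = fk.loso_folds(subjects)
        assert len(folds) == 5
        all_test = np.concatenate([f.test_idx for f in folds])
        assert sorted(all_test.tolist()) == list(range(len(subjects)))
        for fold in folds:
            assert set(fold.train_idx).isdisjoint(fold.test_idx)
            assert set(subjects[fold.test_idx]) == {fold.subject_id}
            assert fold.subject_id not in set(subjects[fold.train_idx])

    def test_full_design_gives_35_folds_of_15(self):
        subjects = np.repeat([f"S{i:02d}" for i in range(35)], 15)
        folds = fk.loso_folds(subjects)
        assert len(folds) == 35
        assert all(len(f.test_idx) == 15 for f in folds)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            fk.loso_folds(np.array(["S0"] * 10))


class TestStandardize:
    def test_train_columns_zero_mean_unit_population_sd(self):
        rng = np.random.default_rng(0)
        train = rng.normal(3.0, 5.0, size=(50, 4))
        test = rng.normal(size=(10, 4))
        train_z, _ = fk.standardize(train, test)
        assert np.allclose(train_z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(train_z.std(axis=0), 1.0, atol=1e-12)

    def test_constant_train_feature_maps_to_zero_everywhere(self):
        train = np.column_stack([np.full(10, 7.0), np.arange(10.0)])
        test = np.array([[100.0, 3.0]])
        train_z, test_z = fk.standardize(train, test)
        assert np.all(train_z[:, 0] == 0.0)
        assert test_z[0, 0] == 0.0

    def test_test_set_uses_train_statistics(self):
        train = np.array([[0.0], [2.0]])
        test = np.array([[1.0]])
        _, test_z = fk.standardize(train, test)
        assert test_z[0, 0] == 0.0  # (1 - 1) / 1


def brute_force_macro_f1(counts):
    """Independent per-class precision/recall computation."""
    k = counts.shape[0]
    f1s = []
    for i in range(k):
        tp = counts[i, i]
        precision = tp / counts[:, i].sum() if counts[:, i].sum() else 0.0
        recall = tp / counts[i].sum() if counts[i].sum() else 0.0
        if counts[i].sum() == 0 and counts[:, i].sum() == 0:
            continue
        f1s.append(
            2 * precision * recall / (precision + recall) if precision + recall else 0.0
        )
    return float(np.mean(f1s))


class TestMetrics:
    def test_agrees_with_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            k = int(rng.integers(2, 8))
            counts = rng.integers(0, 40, size=(k, k))
            counts[0, 0] += 1  # avoid the all-zero matrix
            cm = ConfusionMatrix(labels=tuple(range(k)), counts=counts)
            acc, f1 = fk.metrics(cm)
            assert acc == pytest.approx(np.trace(counts) / counts.sum())
            assert f1 == pytest.approx(brute_force_macro_f1(counts))

    def test_perfect_diagonal(self):
        cm = ConfusionMatrix(labels=("A", "B"), counts=np.diag([30, 20]))
        assert fk.metrics(cm) == (1.0, 1.0)

    def test_constant_majority_classifier_on_unbalanced_split(self):
        # every sample predicted Fall on a 315/210 split
        cm = ConfusionMatrix(
            labels=("Fall", NO_FALL_LABEL),
            counts=np.array([[315, 0], [210, 0]]),
        )
        acc, f1 = fk.metrics(cm)
        assert acc == pytest.approx(0.6)
        assert f1 == pytest.approx(0.375)


class TestRunLoso:
    def test_full_feature_subset_equals_no_subset(self, small_dataset):
        spec = ModelSpec(family="knn", k=5)
        full = fk.run_loso(small_dataset.with_binary_labels(), spec)
        explicit = fk.run_loso(
            small_dataset.with_binary_labels(),
            spec,
            feature_subset=small_dataset.feature_names,
        )
        assert full.fold_accuracy == explicit.fold_accuracy
        assert np.array_equal(full.confusion.counts, explicit.confusion.counts)

    def test_pooled_confusion_total_equals_dataset_size(self, small_dataset):
        report = fk.run_loso(small_dataset, ModelSpec(family="decision_tree"))
        assert report.confusion.total == small_dataset.X.shape[0]

    def test_permuted_labels_score_near_majority_rate(self, small_dataset):
        rng = np.random.default_rng(21)
        binary = small_dataset.with_binary_labels()
        shuffled = fk.FeatureDataset(
            X=binary.X,
            labels=rng.permutation(binary.labels),
            subjects=binary.subjects,
            feature_names=binary.feature_names,
        )
        report = fk.run_loso(shuffled, ModelSpec(family="knn", k=5))
        # chance agreement for p=0.6 class balance is ~0.5; far from separable
        assert 0.25 <= report.accuracy <= 0.8
        assert report.macro_f1 <= 0.8

    def test_rerun_is_bit_identical(self, small_dataset):
        a = fk.run_loso(small_dataset, ModelSpec(family="linear_svm"))
        b = fk.run_loso(small_dataset, ModelSpec(family="linear_svm"))
        assert a.fold_accuracy == b.fold_accuracy
        assert a.fold_macro_f1 == b.fold_macro_f1
        assert np.array_equal(a.confusion.counts, b.confusion.counts)

    def test_no_subject_leaks_between_train_and_test(self, small_dataset):
        folds = fk.loso_folds(small_dataset.subjects)
        for fold in folds:
            train_subjects = set(small_dataset.subjects[fold.train_idx])
            test_subjects = set(small_dataset.subjects[fold.test_idx])
            assert train_subjects.isdisjoint(test_subjects)


class TestDtImportance:
    def test_perfect_split_scores_half(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 6))
        y = np.array(["A"] * 20 + ["B"] * 20)
        X[:, 1] = np.where(y == "A", -1.0, 1.0)
        model = fk.train(ModelSpec(family="decision_tree"), X, y)
        importances = fk.dt_importance(model)
        assert importances[1] == pytest.approx(0.5)
        assert np.all(np.delete(importances, 1) == 0.0)

    def test_all_importances_non_negative(self, small_dataset):
        table = fk.loso_dt_importance(small_dataset)
        assert (table.per_fold.values >= -1e-15).all()

    def test_non_tree_model_rejected(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 3))
        y = np.array(["A", "B"] * 10)
        model = fk.train(ModelSpec(family="lda"), X, y)
        with pytest.raises(TypeError):
            fk.dt_importance(model)


class TestSelectFeatures:
    def _table(self, means):
        frame = pd.DataFrame([means])  # single fold: mean equals the row
        return ImportanceTable(per_fold=frame)

    def test_strict_threshold_application(self):
        table = self._table({"a": 0.001, "b": 0.0001, "c": 0.00021})
        assert fk.select_features(table) == ["a", "c"]

    def test_value_exactly_at_threshold_excluded(self):
        table = self._table({"a": 0.0002, "b": 0.0003})
        assert fk.select_features(table) == ["b"]

    def test_all_zero_importances_select_nothing(self):
        table = self._table({"a": 0.0, "b": 0.0})
        assert fk.select_features(table) == []


def test_reference_subset_names_exist_in_feature_set():
    assert len(fk.REFERENCE_13_FEATURES) == 13
    assert set(fk.REFERENCE_13_FEATURES) <= set(fk.FEATURE_NAMES)


def test_binary_label_collapse(small_dataset):
    binary = small_dataset.with_binary_labels()
    assert set(binary.labels) == {fk.FALL_LABEL, NO_FALL_LABEL}
    assert np.sum(binary.labels == fk.FALL_LABEL) == np.sum(
        small_dataset.labels == fk.FALL_LABEL
    )
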