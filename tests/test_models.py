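"""Classifiers, metrics and validation schemes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbpred.io_formats import FeatureMatrix, LabeledDataset
from dbpred.models import (
    KernelParams,
    ModelSpec,
    compute_metrics,
    gaussian_kernel,
    jackknife_cv,
    k_fold_cv,
    load_model,
    predict,
    save_model,
    train_classifier,
    train_test_split_stratified,
)


def make_labeled(x, y):
    x = np.asarray(x, dtype=float)
    fm = FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(x.shape[0])],
        feature_names=[f"f{j}" for j in range(x.shape[1])],
        values=x,
    )
    return LabeledDataset(features=fm, labels=np.asarray(y, dtype=int))


@pytest.fixture(scope="module")
def separable():
    """Two well-separated 2-D Gaussian blobs, 10 points per class."""
    rng = np.random.default_rng(1)
    x0 = rng.normal(loc=-3.0, scale=0.3, size=(10, 2))
    x1 = rng.normal(loc=3.0, scale=0.3, size=(10, 2))
    return make_labeled(np.vstack([x0, x1]), [0] * 10 + [1] * 10)


class TestGaussianKernel:
    def test_zero_distance_is_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert gaussian_kernel(x, x, sigma=0.7) == 1.0

    def test_closed_form_at_2sigma_squared(self):
        # ||x1-x2||^2 = 2 sigma^2  ->  exp(-1)
        sigma = 1.5
        x1 = np.zeros(1)
        x2 = np.array([math.sqrt(2.0) * sigma])
        assert gaussian_kernel(x1, x2, sigma) == pytest.approx(math.exp(-1))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=5), rng.normal(size=5)
        k = gaussian_kernel(a, b, sigma=1.0)
        assert k == pytest.approx(gaussian_kernel(b, a, sigma=1.0))
        assert 0.0 < k <= 1.0

    def test_kernel_matrix_symmetric_unit_diagonal(self, rng):
        pts = rng.normal(size=(6, 3))
        K = np.array(
            [[gaussian_kernel(p, q, sigma=2.0) for q in pts] for p in pts]
        )
        np.testing.assert_allclose(K, K.T)
        np.testing.assert_allclose(np.diag(K), np.ones(6))

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError, match="dimension"):
            gaussian_kernel(np.zeros(3), np.zeros(4), sigma=1.0)


class TestMetrics:
    @pytest.mark.parametrize(
        "counts,sn,sp,acc,mcc",
        [
            ((19, 0, 19, 0), 1.0, 1.0, 1.0, 1.0),
            ((5, 5, 5, 5), 0.5, 0.5, 0.5, 0.0),
            # a 38-sample balanced test split: 14/19 positives, 16/19 negatives
            ((14, 3, 16, 5), 0.7368, 0.8421, 0.7895, 0.58),
        ],
    )
    def test_worked_examples(self, counts, sn, sp, acc, mcc):
        rep = compute_metrics(*counts)
        assert rep.sn == pytest.approx(sn, abs=5e-5)
        assert rep.sp == pytest.approx(sp, abs=5e-5)
        assert rep.acc == pytest.approx(acc, abs=5e-5)
        assert rep.mcc == pytest.approx(mcc, abs=5e-3)

    def test_zero_denominator_mcc_is_zero(self):
        assert compute_metrics(0, 0, 5, 5).mcc == 0.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(0, 0, 0, 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        tn=st.integers(0, 50), fn=st.integers(0, 50),
    )
    def test_swap_symmetry_and_acc_identity(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        rep = compute_metrics(tp, fp, tn, fn)
        swapped = compute_metrics(tn, fn, tp, fp)
        assert -1.0 <= rep.mcc <= 1.0
        assert rep.mcc == pytest.approx(swapped.mcc, abs=1e-12)
        assert rep.acc == pytest.approx(swapped.acc, abs=1e-12)
        p, n = tp + fn, tn + fp
        if p and n:
            assert rep.acc == pytest.approx((rep.sn * p + rep.sp * n) / (p + n))


class TestTraining:
    @pytest.mark.parametrize("kind", ["svm", "random_forest"])
    def test_separable_training_accuracy(self, separable, kind):
        model = train_classifier(separable, ModelSpec(kind=kind), seed=1)
        pred = predict(model, separable.features)
        assert np.array_equal(pred, separable.labels)

    def test_shuffled_labels_give_chance_cv(self, separable):
        rng = np.random.default_rng(4)
        null = make_labeled(
            np.random.default_rng(4).normal(size=(40, 5)),
            rng.permutation(np.tile([0, 1], 20)),
        )
        acc, _ = k_fold_cv(null, k=10, seed=4)
        assert 0.3 <= acc <= 0.7

    def test_single_class_rejected(self):
        ds = make_labeled(np.random.default_rng(0).normal(size=(8, 2)), np.ones(8))
        with pytest.raises(ValueError):
            train_classifier(ds)

    def test_feature_mismatch_named(self, separable):
        model = train_classifier(separable, seed=1)
        bad = FeatureMatrix(["s0"], ["f0", "other"], np.zeros((1, 2)))
        with pytest.raises(ValueError, match="f1"):
            predict(model, bad)

    def test_empty_matrix_predicts_empty(self, separable):
        model = train_classifier(separable, seed=1)
        empty = FeatureMatrix([], ["f0", "f1"], np.zeros((0, 2)))
        assert predict(model, empty).size == 0

    def test_row_permutation_permutes_predictions(self, separable):
        model = train_classifier(separable, seed=1)
        base = predict(model, separable.features)
        perm = np.random.default_rng(2).permutation(separable.n_samples)
        shuffled = FeatureMatrix(
            [separable.features.sample_ids[i] for i in perm],
            list(separable.features.feature_names),
            separable.features.values[perm],
        )
        np.testing.assert_array_equal(predict(model, shuffled), base[perm])

    def test_model_round_trips_through_file(self, separable, tmp_path):
        model = train_classifier(separable, seed=1)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(
            predict(loaded, separable.features), predict(model, separable.features)
        )


class TestValidationSchemes:
    def test_kfold_on_separable_data(self, separable):
        acc, reports = k_fold_cv(separable, k=10, seed=1)
        assert acc >= 0.9
        assert len(reports) == 10

    def test_seed_invariance_on_separable_data(self, separable):
        acc1, _ = k_fold_cv(separable, k=5, seed=1)
        acc2, _ = k_fold_cv(separable, k=5, seed=99)
        assert acc1 == acc2 == 1.0

    def test_jackknife_perfect_on_separable(self, separable):
        rep = jackknife_cv(separable)
        assert rep.acc == 1.0
        assert rep.tp + rep.fp + rep.tn + rep.fn == separable.n_samples

    def test_jackknife_equals_k_equal_n_fold(self, separable):
        rep = jackknife_cv(separable)
        _, fold_reports = k_fold_cv(separable, k=separable.n_samples, seed=0)
        pooled_tp = sum(r.tp for r in fold_reports)
        pooled_tn = sum(r.tn for r in fold_reports)
        assert (pooled_tp, pooled_tn) == (rep.tp, rep.tn)

    def test_too_few_samples_for_jackknife(self):
        ds = make_labeled(np.zeros((2, 1)), [0, 1])
        with pytest.raises(ValueError):
            jackknife_cv(ds)

    def test_class_smaller_than_k_rejected(self, separable):
        with pytest.raises(ValueError, match="folds"):
            k_fold_cv(separable, k=15)


class TestStratifiedSplit:
    def test_186_balanced_split(self):
        ds = make_labeled(
            np.random.default_rng(0).normal(size=(186, 3)),
            np.repeat([1, 0], 93),
        )
        train, test = train_test_split_stratified(ds, 0.8, seed=0)
        assert train.n_samples == 148 and test.n_samples == 38
        assert np.bincount(train.labels).tolist() == [74, 74]
        assert np.bincount(test.labels).tolist() == [19, 19]

    def test_even_split(self):
        ds = make_labeled(np.zeros((10, 1)), np.tile([0, 1], 5))
        train, test = train_test_split_stratified(ds, 0.5, seed=1)
        assert train.n_samples == test.n_samples == 5

    def test_partition_property(self):
        ds = make_labeled(
            np.random.default_rng(3).normal(size=(30, 2)), np.tile([0, 1], 15)
        )
        train, test = train_test_split_stratified(ds, 0.7, seed=3)
        ids = set(train.features.sample_ids) | set(test.features.sample_ids)
        assert ids == set(ds.features.sample_ids)
        assert not set(train.features.sample_ids) & set(test.features.sample_ids)

    def test_emptying_split_rejected(self):
        ds = make_labeled(np.zeros((4, 1)), [0, 0, 1, 1])
        with pytest.raises(ValueError):
            train_test_split_stratified(ds, 0.95, seed=0)
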