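"""Split arithmetic, fold partitioning, training loop behavior, blind test."""

import datetime

import numpy as np
import pytest

from actimage.cnn import ArchitectureSpec, LayerKind, LayerSpec
from actimage.preprocess import EncodedImage, LabeledDataset
from actimage.training import (
    FoldResult,
    SplitConfig,
    blind_test,
    kfold_partition,
    stratified_split,
    train_fold,
    underfit_check,
)


def make_dataset(class_sizes, rng, subjects_per_class=None):
    """Noise day-images with given per-class counts (and optional subjects)."""
    images = []
    for label, n in enumerate(class_sizes):
        n_subj = subjects_per_class or n
        for i in range(n):
            images.append(
                EncodedImage(
                    pixels=rng.uniform(0, 255, (30, 48)),
                    label=label,
                    subject_id=f"c{label}_s{i % n_subj}",
                    date=datetime.date(2020, 1, 1) + datetime.timedelta(days=i),
                )
            )
    return LabeledDataset(images)


def tiny_arch(h=30, w=48):
    return ArchitectureSpec(
        layers=[
            LayerSpec(LayerKind.MAXPOOL, kernel=6, stride=6),
            LayerSpec(LayerKind.FLATTEN),
            LayerSpec(LayerKind.DENSE, width=3),
            LayerSpec(LayerKind.SOFTMAX),
        ],
        input_shape=(h, w, 1),
    )


class TestStratifiedSplit:
    def test_seventy_percent_of_1436_is_1005(self, rng):
        # published cohort shape: 697 control, 371 depression, 368 schizophrenia
        ds = make_dataset([697, 371, 368], rng)
        train, test = stratified_split(ds, SplitConfig(seed=0))
        assert len(train) == 1005
        assert len(test) == 431

    def test_even_split_is_exact_per_class(self, rng):
        ds = make_dataset([10, 10, 10], rng)
        train, test = stratified_split(ds, SplitConfig(train_fraction=0.5, seed=1))
        for part in (train, test):
            assert part.class_counts == {0: 5, 1: 5, 2: 5}

    def test_partition_is_disjoint_and_exhaustive(self, rng):
        ds = make_dataset([13, 9, 21], rng)
        train, test = stratified_split(ds, SplitConfig(seed=3))
        key = lambda im: (im.subject_id, im.date, im.label)
        train_keys = {key(im) for im in train.images}
        test_keys = {key(im) for im in test.images}
        assert not train_keys & test_keys
        assert len(train_keys | test_keys) == len(ds)

    def test_reproducible_under_seed(self, rng):
        ds = make_dataset([20, 20, 20], rng)
        a_train, _ = stratified_split(ds, SplitConfig(seed=9))
        b_train, _ = stratified_split(ds, SplitConfig(seed=9))
        assert [im.date for im in a_train.images] == [im.date for im in b_train.images]

    def test_group_by_subject_prevents_leakage(self, rng):
        ds = make_dataset([40, 40, 40], rng, subjects_per_class=8)
        train, test = stratified_split(
            ds, SplitConfig(seed=2, group_by_subject=True)
        )
        assert not set(train.subject_ids) & set(test.subject_ids)

    def test_tiny_class_rejected(self, rng):
        ds = make_dataset([5, 5, 1], rng)
        with pytest.raises(ValueError):
            stratified_split(ds, SplitConfig())


class TestKfoldPartition:
    def test_nine_images_three_folds(self, rng):
        folds = kfold_partition(make_dataset([3, 3, 3], rng), k=3, seed=0)
        assert sorted(len(f) for f in folds) == [3, 3, 3]

    def test_ten_images_three_folds(self, rng):
        folds = kfold_partition(make_dataset([4, 3, 3], rng), k=3, seed=0)
        assert sorted(len(f) for f in folds) == [3, 3, 4]

    @pytest.mark.parametrize("sizes", [[9, 6, 6], [10, 7, 5], [8, 8, 9]])
    def test_validation_folds_cover_training_set(self, sizes, rng):
        ds = make_dataset(sizes, rng)
        folds = kfold_partition(ds, k=3, seed=4)
        combined = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(combined, np.arange(len(ds)))

    def test_k_below_two_rejected(self, rng):
        with pytest.raises(ValueError):
            kfold_partition(make_dataset([5, 5, 5], rng), k=1)


class TestTrainFold:
    def test_zero_epochs_gives_chance_level(self, rng):
        ds = make_dataset([20, 20, 20], rng)
        cfg = SplitConfig(epochs=0, seed=0)
        result = train_fold(tiny_arch(), ds, ds, cfg)
        assert result.train_loss == [] and result.val_acc == []
        assert 0.1 <= result.accuracy <= 0.6  # noise inputs, untrained weights

    def test_curve_lengths_equal_epochs(self, rng):
        ds = make_dataset([8, 8, 8], rng)
        cfg = SplitConfig(epochs=2, seed=0)
        result = train_fold(tiny_arch(), ds, ds, cfg)
        for curve in (result.train_loss, result.train_acc, result.val_loss, result.val_acc):
            assert len(curve) == 2

    def test_deterministic_under_seed(self, rng):
        ds = make_dataset([8, 8, 8], rng)
        cfg = SplitConfig(epochs=2, seed=7)
        a = train_fold(tiny_arch(), ds, ds, cfg)
        b = train_fold(tiny_arch(), ds, ds, cfg)
        assert a.train_loss == b.train_loss
        assert a.val_acc == b.val_acc


class TestUnderfitCheck:
    def _result(self, train, val):
        return FoldResult(0, [train], [0.5], [val], [0.5], None, 0.5, None)

    def test_similar_losses_acceptable(self):
        assert underfit_check(self._result(0.30, 0.31)).verdict == "acceptable"

    def test_validation_below_training_flags_underfit(self):
        assert underfit_check(self._result(0.50, 0.20)).verdict == "underfit"

    def test_validation_far_above_flags_overfit(self):
        assert underfit_check(self._result(0.10, 0.90)).verdict == "overfit-suspect"

    def test_empty_curves_rejected(self):
        with pytest.raises(ValueError):
            underfit_check(self._result(0.1, 0.1).__class__(0, [], [], [], [], None, 0, None))


class _StubModel:
    """Fixed-prediction classifier for report plumbing tests."""

    def __init__(self, predictions):
        self._pred = np.asarray(predictions)

    def predict(self, x, batch_size=32):
        return self._pred[: len(x)]


class TestBlindTest:
    def test_perfect_classifier_diagonal(self, rng):
        ds = make_dataset([4, 4, 4], rng)
        report = blind_test(_StubModel(ds.labels), ds)
        assert np.trace(report.confusion.counts) == 12
        assert report.accuracy == 1.0
        assert report.inference_seconds_per_batch >= 0
        assert report.peak_memory_mb > 0

    def test_constant_classifier_on_balanced_set(self, rng):
        ds = make_dataset([5, 5, 5], rng)
        report = blind_test(_StubModel(np.zeros(15, dtype=int)), ds)
        assert report.accuracy == pytest.approx(1 / 3)

    def test_report_recounts_from_stored_predictions(self, rng):
        ds = make_dataset([6, 5, 4], rng)
        preds = rng.integers(0, 3, size=len(ds))
        report = blind_test(_StubModel(preds), ds)
        from actimage.metrics import confusion

        recount = confusion(ds.labels, report.predictions)
        np.testing.assert_array_equal(recount.counts, report.confusion.counts)

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            blind_test(_StubModel([]), LabeledDataset([]))
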