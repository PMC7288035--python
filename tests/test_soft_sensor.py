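import dataclasses

import numpy as np
import pytest

from eegsm import (ClassifierSpec, ConfusionMatrix, ImageSet, LeakageError,
                   SoftSensor, accuracy, build_classifier, evaluate,
                   plan_split, shuffle_labels, train)
from eegsm.montage import CATEGORIES
from eegsm.soft_sensor import SplitError, predict_proba


def _synthetic_images(n_pairs=4, per_pair=12, size=16, seed=0):
    """Tiny labelled images: the class lights up one image quadrant."""
    rng = np.random.default_rng(seed)
    h = size // 2
    quadrants = [(slice(0, h), slice(0, h)), (slice(0, h), slice(h, None)),
                 (slice(h, None), slice(0, h)), (slice(h, None), slice(h, None))]
    images, labels, pairs = [], [], []
    for pair in range(n_pairs):
        for k in range(per_pair):
            label = k % 4
            img = rng.integers(0, 60, (size, size, 3))
            r, c = quadrants[label]
            img[r, c] += 180
            images.append(img.astype(np.uint8))
            labels.append(label)
            pairs.append(pair)
    return ImageSet(np.stack(images), np.array(labels), np.array(pairs))


class TestSplitPlan:
    def test_study_scale_split_counts(self):
        plan = plan_split(list(range(14)), 10, 2, 2, seed=0)
        assert plan.counts == {"train": 10, "validation": 2, "test": 2}
        # 120 images per recording x 4 recordings per pair
        images_per_pair = 4 * 120
        assert len(plan.pairs("train")) * images_per_pair == 4800
        assert len(plan.pairs("validation")) * images_per_pair == 960
        assert len(plan.pairs("test")) * images_per_pair == 960

    def test_small_split_counts(self):
        plan = plan_split(list(range(4)), 2, 1, 1, seed=1)
        images_per_pair = 4 * 120
        assert len(plan.pairs("train")) * images_per_pair == 960
        assert len(plan.pairs("validation")) * images_per_pair == 480
        assert len(plan.pairs("test")) * images_per_pair == 480

    def test_deterministic_and_seed_sensitive(self):
        a = plan_split(list(range(14)), 10, 2, 2, seed=5)
        b = plan_split(list(range(14)), 10, 2, 2, seed=5)
        assert a.assignment == b.assignment
        seen = {tuple(sorted(plan_split(list(range(14)), 10, 2, 2, seed=s).pairs("test")))
                for s in range(10)}
        assert len(seen) > 1

    def test_partition_is_exhaustive_and_disjoint(self):
        plan = plan_split(list(range(14)), 10, 2, 2, seed=3)
        all_pairs = (plan.pairs("train") + plan.pairs("validation")
                     + plan.pairs("test"))
        assert sorted(all_pairs) == list(range(14))

    def test_mismatched_counts_are_rejected(self):
        with pytest.raises(SplitError):
            plan_split(list(range(14)), 10, 2, 1, seed=0)


class TestClassifierContract:
    def test_outputs_are_probabilities(self):
        spec = ClassifierSpec(input_size=16, conv_filters=(2, 2, 2, 2),
                              dense_width=8)
        model = build_classifier(spec, seed=0)
        x = np.random.default_rng(0).integers(0, 255, (3, 16, 16, 3), dtype=np.uint8)
        p = predict_proba(model, x)
        assert p.shape == (3, 4)
        assert np.all(p >= 0)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_fixed_seed_gives_deterministic_outputs(self):
        spec = ClassifierSpec(input_size=16, conv_filters=(2, 2, 2, 2),
                              dense_width=8)
        x = np.random.default_rng(1).integers(0, 255, (2, 16, 16, 3), dtype=np.uint8)
        pa = predict_proba(build_classifier(spec, seed=7), x)
        pb = predict_proba(build_classifier(spec, seed=7), x)
        assert np.array_equal(pa, pb)

    def test_parameter_count_matches_layer_arithmetic(self):
        """Hand-computed oracle over the layer dimensions."""
        spec = ClassifierSpec(input_size=90, conv_filters=(8, 16, 32, 64),
                              dense_width=64)
        model = build_classifier(spec, seed=0)
        conv = (3 * 3 * 3 * 8 + 8) + (3 * 3 * 8 * 16 + 16) \
            + (3 * 3 * 16 * 32 + 32) + (3 * 3 * 32 * 64 + 64)
        # 90 -> 45 -> 22 -> 11 -> 5 after four 2x2 pools
        dense = (5 * 5 * 64) * 64 + 64
        out = 64 * 4 + 4
        assert model.n_parameters() == conv + dense + out

    def test_wrong_image_shape_is_rejected_at_fit(self):
        images = _synthetic_images(size=12)
        spec = ClassifierSpec(input_size=16, conv_filters=(2, 2, 2, 2),
                              dense_width=8, epochs=1)
        plan = plan_split(list(range(4)), 2, 1, 1, seed=0)
        with pytest.raises(ValueError, match="shape"):
            SoftSensor(spec).fit(images, plan)


class TestTraining:
    SPEC = ClassifierSpec(input_size=16, conv_filters=(4, 4, 4, 4),
                          dense_width=16, epochs=2, patience=5, batch_size=8)

    def test_two_epoch_run_records_history_of_length_two(self):
        images = _synthetic_images()
        plan = plan_split(list(range(4)), 2, 1, 1, seed=0)
        res = train(images, plan, self.SPEC, seed=0)
        assert len(res.history) == 2
        assert len(res.history.val_loss) == 2

    def test_learnable_quadrant_code_is_learned(self):
        """Small-scale pilot contract: a lit image quadrant that encodes the
        label should be classified near-perfectly on held-out data within
        the epoch budget."""
        images = _synthetic_images(per_pair=40)
        plan = plan_split(list(range(4)), 2, 1, 1, seed=0)
        spec = dataclasses.replace(self.SPEC, epochs=14)
        res = train(images, plan, spec, seed=0)
        assert max(res.history.val_accuracy) > 0.9
        assert res.history.train_accuracy[-1] > 2 * 0.25  # well above chance

    def test_contaminated_training_stream_raises_leakage_error(self):
        images = _synthetic_images()
        plan = plan_split(list(range(4)), 2, 1, 1, seed=0)
        test_pair = plan.pairs("test")[0]
        val = images.for_split(plan, "validation")
        train_ok = images.for_split(plan, "train")
        leaked = images.subset(images.pair_ids == test_pair)
        contaminated = ImageSet(
            np.concatenate([train_ok.images, leaked.images]),
            np.concatenate([train_ok.labels, leaked.labels]),
            np.concatenate([train_ok.pair_ids, leaked.pair_ids]),
        )
        with pytest.raises(LeakageError, match=str(test_pair)):
            SoftSensor(self.SPEC).fit_streams(
                contaminated, val, set(plan.pairs("test")), seed=0)

    def test_test_pair_in_validation_stream_is_also_rejected(self):
        images = _synthetic_images()
        plan = plan_split(list(range(4)), 2, 1, 1, seed=0)
        train_ok = images.for_split(plan, "train")
        bad_val = images.for_split(plan, "test")
        with pytest.raises(LeakageError):
            SoftSensor(self.SPEC).fit_streams(
                train_ok, bad_val, set(plan.pairs("test")), seed=0)

    def test_determinism_of_fit(self):
        images = _synthetic_images()
        plan = plan_split(list(range(4)), 2, 1, 1, seed=0)
        a = train(images, plan, self.SPEC, seed=3)
        b = train(images, plan, self.SPEC, seed=3)
        assert a.history.train_loss == b.history.train_loss
        for wa, wb in zip(a.model.params, b.model.params):
            assert np.array_equal(wa, wb)


class TestEvaluation:
    def test_perfect_predictions_give_diagonal_matrix(self):
        true = np.array([0, 1, 2, 3, 0, 1])
        cm = ConfusionMatrix.from_predictions(true, true)
        assert np.array_equal(cm.counts, np.diag([2, 2, 1, 1]))
        assert accuracy(cm) == 1.0

    def test_constant_predictor_fills_one_column(self):
        true = np.array([0, 1, 2, 3])
        pred = np.zeros(4, dtype=int)
        cm = ConfusionMatrix.from_predictions(true, pred)
        assert np.array_equal(cm.counts[:, 0], np.ones(4, dtype=int))
        assert cm.counts[:, 1:].sum() == 0
        assert accuracy(cm) == 0.25

    def test_row_sums_equal_per_category_counts(self):
        rng = np.random.default_rng(0)
        true = rng.integers(0, 4, 100)
        pred = rng.integers(0, 4, 100)
        cm = ConfusionMatrix.from_predictions(true, pred)
        for k in range(4):
            assert cm.counts[k].sum() == int((true == k).sum())
        assert cm.total == 100

    def test_accuracy_hand_arithmetic(self):
        cm = ConfusionMatrix(np.array([[50, 10, 0, 0], [5, 55, 0, 0],
                                       [0, 0, 60, 0], [0, 0, 20, 40]]))
        assert accuracy(cm) == pytest.approx(205 / 240)

    def test_accuracy_matches_trace_over_total_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = rng.integers(0, 50, (4, 4))
            if counts.sum() == 0:
                continue
            cm = ConfusionMatrix(counts)
            assert accuracy(cm) == pytest.approx(
                np.trace(counts) / counts.sum(), abs=1e-15)

    def test_accuracy_invariant_to_evaluation_order(self):
        images = _synthetic_images()
        spec = TestTraining.SPEC
        plan = plan_split(list(range(4)), 2, 1, 1, seed=0)
        res = train(images, plan, spec, seed=0)
        test = images.for_split(plan, "test")
        cm1 = evaluate(res.model, test)
        order = np.random.default_rng(0).permutation(len(test))
        cm2 = evaluate(res.model, test.subset(order))
        assert accuracy(cm1) == accuracy(cm2)

    def test_empty_matrix_is_rejected(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionMatrix(np.zeros((4, 4), dtype=int)))

    def test_shuffle_labels_permutes_only_labels(self):
        images = _synthetic_images()
        sh = shuffle_labels(images, seed=1)
        assert np.array_equal(sh.images, images.images)
        assert np.array_equal(sh.pair_ids, images.pair_ids)
        assert sorted(sh.labels) == sorted(images.labels)
        assert not np.array_equal(sh.labels, images.labels)


def test_category_order_is_fixed():
    assert CATEGORIES == ("HKT_PO", "HKT_Leader", "BSC_PO", "BSC_Leader")
    cm = ConfusionMatrix(np.zeros((4, 4), dtype=int))
    assert cm.categories == CATEGORIES
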