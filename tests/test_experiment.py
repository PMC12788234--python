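"""Protocol machinery: loss, splits, metrics, training loop, Model/Results."""

import numpy as np
import pytest

from semgintent.config import TrainConfig
from semgintent.experiment import (
    FeatureSet,
    MotionIntentModel,
    assert_no_leakage,
    confusion_matrix,
    evaluate,
    kfold_split,
    metrics_from_confusion,
    train_model,
)
from semgintent.fusion import build_variant
from semgintent.nn import cross_entropy, softmax

RNG = np.random.default_rng(8)


def _tiny_features(n, n_scales=5, window=320, bins=41, chans=3, classes=(1, 2, 3, 4),
                   seed=0):
    rng = np.random.default_rng(seed)
    labels = rng.choice(classes, size=n)
    # class-dependent mean shift so the tiny net has something to learn
    tf = rng.standard_normal((n, n_scales, window, chans)).astype(np.float32)
    tf += labels[:, None, None, None] * 0.5
    return FeatureSet(
        tfmap=tf,
        spectrum=np.abs(rng.standard_normal((n, bins, chans))).astype(np.float32),
        labels=labels.astype(np.int64),
        trial_ids=np.array([f"T{seed}_{i % 7}" for i in range(n)]),
        starts=np.arange(n) * 200,
        subject_ids=np.array(["S0"] * n),
    )


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        y = np.eye(17)[[0, 3, 9]]
        assert cross_entropy(y, y) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_over_17_classes_is_ln17(self):
        y = np.eye(17)[[0, 5]]
        p = np.full((2, 17), 1 / 17)
        assert cross_entropy(y, p) == pytest.approx(np.log(17), abs=1e-6)
        assert np.log(17) == pytest.approx(2.8332, abs=1e-4)

    def test_row_duplication_invariance(self):
        y = np.eye(5)[[0, 2]]
        p = softmax(RNG.standard_normal((2, 5)))
        doubled = cross_entropy(np.repeat(y, 2, axis=0), np.repeat(p, 2, axis=0))
        assert cross_entropy(y, p) == pytest.approx(doubled, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cross_entropy(np.eye(5), np.eye(4))


class TestKFold:
    def test_ten_trials_split_7_1_2(self, small_trials):
        folds = kfold_split(small_trials, k=5, seed=0)
        assert len(folds) == 5
        for f in folds:
            assert len(f.train_ids) == 7
            assert len(f.val_ids) == 1
            assert len(f.test_ids) == 2
            assert not set(f.train_ids) & set(f.test_ids)
            assert not set(f.val_ids) & set(f.test_ids)

    def test_test_sets_rotate_and_cover_all_trials(self, small_trials):
        folds = kfold_split(small_trials, k=5, seed=0)
        all_ids = {t.trial_id for t in small_trials}
        union = set().union(*(f.test_ids for f in folds))
        assert union == all_ids
        tests = [frozenset(f.test_ids) for f in folds]
        assert len(set(tests)) == 5

    def test_same_seed_identical_folds(self, small_trials):
        assert kfold_split(small_trials, seed=3) == kfold_split(small_trials, seed=3)
        assert kfold_split(small_trials, seed=3) != kfold_split(small_trials, seed=4)

    def test_too_few_trials_rejected(self, small_trials):
        with pytest.raises(ValueError, match="at least 10"):
            kfold_split(small_trials[:8], k=5, seed=0)


class TestMetrics:
    def test_hand_computed_two_class_confusion(self):
        cm = np.array([[9, 1], [2, 8]])
        m = metrics_from_confusion(cm)
        assert m["accuracy"] == pytest.approx(85.0)
        assert m["precision"] == pytest.approx(100 * (9 / 11 + 8 / 9) / 2, abs=0.01)
        assert m["recall"] == pytest.approx(85.0)

    def test_perfect_predictor(self):
        y = RNG.integers(1, 18, 100)
        cm = confusion_matrix(y, y)
        m = metrics_from_confusion(cm)
        assert m["accuracy"] == 100.0
        assert m["f1"] == 100.0
        assert np.all(cm - np.diag(np.diag(cm)) == 0)

    def test_all_one_class_predictor_on_balanced_set(self):
        y_true = np.array([1] * 10 + [2] * 10)
        y_pred = np.ones(20, dtype=int)
        m = metrics_from_confusion(confusion_matrix(y_true, y_pred))
        assert m["accuracy"] == pytest.approx(50.0)
        assert m["recall"] == pytest.approx(50.0)

    def test_accuracy_equals_trace_over_total(self):
        cm = confusion_matrix(RNG.integers(1, 18, 200), RNG.integers(1, 18, 200))
        m = metrics_from_confusion(cm)
        assert m["accuracy"] == pytest.approx(100 * np.trace(cm) / cm.sum())
        assert cm.sum() == 200


class TestLeakageGuard:
    def test_overlap_raises(self):
        a = _tiny_features(6)
        with pytest.raises(AssertionError, match="leakage"):
            assert_no_leakage(a, _tiny_features(4, seed=1), a)


class TestTrainLoop:
    def _net(self, tiny_model_config, seed=0):
        return build_variant("baseline", tiny_model_config, seed=seed)

    def test_zero_lr_leaves_weights_unchanged(self, tiny_model_config):
        net = self._net(tiny_model_config)
        before = {k: v.copy() for k, v in net.state_dict().items()
                  if "running" not in k}
        tcfg = TrainConfig(epochs=1, lr=0.0, batch_size=8, seed=0)
        train_model(net, _tiny_features(16), _tiny_features(8, seed=1), tcfg)
        after = net.state_dict()
        for k, v in before.items():
            np.testing.assert_array_equal(v, after[k], err_msg=k)

    def test_patience_zero_runs_exactly_one_epoch(self, tiny_model_config):
        net = self._net(tiny_model_config)
        tcfg = TrainConfig(epochs=50, early_stop_patience=0, batch_size=8, seed=0)
        hist = train_model(net, _tiny_features(16), _tiny_features(8, seed=1), tcfg)
        assert len(hist["train_loss"]) == 1

    def test_run_twice_determinism(self, tiny_model_config):
        tcfg = TrainConfig(epochs=3, batch_size=8, seed=7, early_stop_patience=10)
        vals = []
        for _ in range(2):
            net = self._net(tiny_model_config, seed=7)
            hist = train_model(net, _tiny_features(24), _tiny_features(8, seed=1), tcfg)
            vals.append(hist["val_loss"])
        assert vals[0] == vals[1]

    def test_empty_validation_rejected(self, tiny_model_config):
        net = self._net(tiny_model_config)
        empty = _tiny_features(4).subset(np.zeros(4, dtype=bool))
        with pytest.raises(ValueError, match="non-empty"):
            train_model(net, _tiny_features(8), empty, TrainConfig(epochs=1))


class TestModelResults:
    def test_fit_evaluate_summary(self, tiny_model_config, tiny_ifia_config):
        model = MotionIntentModel(
            _tiny_features(32, seed=0), _tiny_features(12, seed=1),
            variant="baseline", model_config=tiny_model_config,
            ifia_config=tiny_ifia_config,
        )
        res = model.fit(TrainConfig(epochs=2, batch_size=16, seed=0))
        test = _tiny_features(10, seed=2)
        fold = res.evaluate(test)
        assert fold.confusion.shape == (4, 4)
        assert fold.confusion.sum() == 10
        assert 0 <= fold.accuracy <= 100
        text = res.summary()
        assert "baseline" in text and "trainable parameters" in text

    def test_loss_round_trip_on_exported_probabilities(self, tiny_model_config):
        model = MotionIntentModel(
            _tiny_features(16, seed=0), _tiny_features(8, seed=1),
            variant="baseline", model_config=tiny_model_config,
        )
        res = model.fit(TrainConfig(epochs=1, batch_size=8, seed=0))
        test = _tiny_features(10, seed=2)
        probs = res.predict_proba(test)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        y1h = np.eye(tiny_model_config.n_classes)[test.labels - 1]
        manual = cross_entropy(y1h, probs)
        from semgintent.experiment import _batched_loss
        assert manual == pytest.approx(_batched_loss(res.network, test), rel=1e-5)

    def test_empty_test_set_rejected(self, tiny_model_config):
        net = build_variant("baseline", tiny_model_config, seed=0)
        empty = _tiny_features(4).subset(np.zeros(4, dtype=bool))
        with pytest.raises(ValueError, match="empty test set"):
            evaluate(net, empty)
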