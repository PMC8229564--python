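import warnings

import numpy as np
import pytest
from scipy import stats as sps

from isletpol.segmentation import (
    CrossValConfig,
    UNetConfig,
    build_unet,
    cross_validate,
    evaluate,
    iou,
    make_training_pairs,
    predict_mask,
    predict_proba,
    train,
)
from isletpol.synthetic import SynthParams, generate_islet
from oracles import brute_confusion_metrics

TINY = UNetConfig(input_size=32, in_channels=2, depth=2, base_filters=4, seed=0)


def _toy_pairs(n, size=64, seed=0):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        islets = [
            generate_islet(SynthParams(image_size=size, n_cells=8, seed=seed + i))
            for i in range(n)
        ]
    return make_training_pairs(islets)


class TestBuildUnet:
    def test_output_shape_matches_input(self):
        model = build_unet(TINY)
        x = np.random.default_rng(0).random((1, 2, 32, 32), dtype=np.float32)
        assert model.forward(x).shape == (1, 1, 32, 32)

    def test_probabilities_in_unit_interval(self):
        model = build_unet(TINY)
        prob = predict_proba(model, np.random.default_rng(1).random((2, 32, 32)))
        assert prob.shape == (32, 32)
        assert (prob > 0).all() and (prob < 1).all()

    def test_untrained_predictions_reproducible_under_seed(self):
        x = np.random.default_rng(2).random((2, 32, 32))
        p1 = predict_proba(build_unet(TINY), x)
        p2 = predict_proba(build_unet(TINY), x)
        np.testing.assert_array_equal(p1, p2)

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_unet(UNetConfig(input_size=100, depth=3))


class TestPredictMask:
    def test_constant_probability_below_threshold_gives_empty_mask(self):
        model = build_unet(TINY)
        for conv in model._conv_layers():
            conv.W[...] = 0
            conv.b[...] = 0
        model.head.b[...] = np.log(0.4 / 0.6)  # sigmoid -> 0.40 everywhere
        x = np.random.default_rng(3).random((2, 32, 32))
        assert predict_proba(model, x) == pytest.approx(0.4, abs=1e-6)
        assert not predict_mask(model, x).any()

    def test_threshold_separates_mixed_map(self):
        model = build_unet(TINY)
        prob = np.where(np.arange(32 * 32).reshape(32, 32) % 2 == 0, 0.4, 0.6)
        mask = (prob > model.cfg.threshold).astype(np.uint8)
        assert set(np.unique(mask)) == {0, 1}

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="input_size"):
            predict_proba(build_unet(TINY), np.zeros((2, 16, 16)))


class TestEvaluate:
    def test_perfect_prediction(self):
        truth = np.random.default_rng(4).random((16, 16)) > 0.5
        m = evaluate(truth, truth)
        assert m.accuracy == m.precision == m.recall == m.f1 == 1.0

    def test_empty_prediction_convention(self):
        truth = np.ones((8, 8), bool)
        m = evaluate(np.zeros((8, 8), bool), truth)
        assert m.recall == 0.0 and m.precision == 0.0 and m.f1 == 0.0

    def test_known_confusion_counts(self):
        # 4x4 with TP=2, FP=1, FN=1, TN=12
        truth = np.zeros((4, 4), bool)
        pred = np.zeros((4, 4), bool)
        truth[0, 0] = truth[0, 1] = truth[0, 2] = True
        pred[0, 0] = pred[0, 1] = pred[1, 0] = True
        m = evaluate(pred, truth)
        assert m.precision == pytest.approx(2 / 3)
        assert m.recall == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(2 / 3)
        assert m.accuracy == pytest.approx(14 / 16)

    def test_matches_brute_force_oracle_on_random_masks(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            pred = rng.random((12, 12)) > rng.random()
            truth = rng.random((12, 12)) > rng.random()
            m = evaluate(pred, truth)
            ref = brute_confusion_metrics(pred, truth)
            for key in ("accuracy", "precision", "recall", "f1"):
                assert getattr(m, key) == pytest.approx(ref[key])
            # F1 identity
            if m.precision + m.recall > 0:
                expected = 2 * m.precision * m.recall / (m.precision + m.recall)
                assert m.f1 == pytest.approx(expected)

    def test_loss_is_cross_entropy_of_probability_map(self):
        truth = np.array([[1, 0], [1, 1]], bool)
        prob = np.array([[0.9, 0.2], [0.6, 0.99]])
        m = evaluate(prob > 0.5, truth, prob=prob)
        expected = -np.mean(
            np.log([0.9, 0.8, 0.6, 0.99])
        )
        assert m.loss == pytest.approx(expected)


class TestTrain:
    def test_single_epoch_history(self):
        pairs = _toy_pairs(4, size=64)
        cfg = UNetConfig(input_size=64, epochs_max=1, base_filters=4, seed=0)
        _, history = train(build_unet(cfg), pairs[:3], pairs[3:], cfg)
        assert len(history) == 1
        assert history[0]["epoch"] == 1

    def test_validation_loss_improves_on_toy_task(self):
        pairs = _toy_pairs(10, size=64, seed=50)
        cfg = UNetConfig(input_size=64, epochs_max=8, base_filters=4, learning_rate=1e-2, seed=1)
        _, history = train(build_unet(cfg), pairs[:8], pairs[8:], cfg)
        assert min(h["val_loss"] for h in history) < history[0]["val_loss"]

    def test_reproducible_given_seed_and_data(self):
        pairs = _toy_pairs(6, size=64, seed=60)
        cfg = UNetConfig(input_size=64, epochs_max=2, base_filters=4, seed=2)
        _, h1 = train(build_unet(cfg), pairs[:5], pairs[5:], cfg)
        _, h2 = train(build_unet(cfg), pairs[:5], pairs[5:], cfg)
        assert h1 == h2

    def test_empty_training_set_rejected(self):
        cfg = UNetConfig(input_size=64, base_filters=4)
        with pytest.raises(ValueError, match="empty"):
            train(build_unet(cfg), [], [], cfg)


class TestCrossValidate:
    def test_folds_form_disjoint_cover(self):
        pairs = _toy_pairs(4, size=64)
        cfg = UNetConfig(input_size=64, epochs_max=1, base_filters=2, seed=0)
        result = cross_validate(pairs, CrossValConfig(K=2, seed=0), cfg)
        all_idx = sorted(i for fold in result.fold_indices for i in fold)
        assert all_idx == [0, 1, 2, 3]
        assert len(result.fold_metrics) == 2

    def test_mean_is_arithmetic_mean_of_folds(self):
        pairs = _toy_pairs(4, size=64)
        cfg = UNetConfig(input_size=64, epochs_max=1, base_filters=2, seed=0)
        result = cross_validate(pairs, CrossValConfig(K=2, seed=0), cfg)
        for name in ("accuracy", "precision", "recall", "f1", "epoch"):
            expected = np.mean([getattr(m, name) for m in result.fold_metrics])
            assert getattr(result.mean, name) == pytest.approx(expected)

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            cross_validate(_toy_pairs(3, size=64), CrossValConfig(K=5), TINY)

    def test_toy_cross_validation_reaches_high_accuracy(self):
        pairs = _toy_pairs(9, size=64, seed=70)
        cfg = UNetConfig(
            input_size=64, epochs_max=10, base_filters=4, learning_rate=1e-2,
            early_stop_patience=10, seed=3,
        )
        result = cross_validate(pairs, CrossValConfig(K=3, seed=1), cfg)
        assert result.mean.accuracy > 0.9
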