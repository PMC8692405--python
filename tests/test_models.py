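"""GAP classifier equations, initialisation, training and the segmenter."""

import numpy as np
import pytest

from conftest import split_arrays
from wsus.models import (GapClassifier, GapClassifierConfig, SegmenterConfig,
                         TrainingConfig, UNetSegmenter, class_scores,
                         global_average_pool, grid_search, softmax_pom,
                         train_classifier, train_segmenter)
from wsus.stats import roc_auc

TINY32 = GapClassifierConfig(input_side=32, k_channels=8)


class TestEquations:
    def test_gap_sum_examples(self):
        assert global_average_pool(np.ones((1, 7, 7)))[0] == 49
        assert global_average_pool(np.zeros((1, 5, 5)))[0] == 0
        assert global_average_pool(np.array([[[1, 2], [3, 4]]]))[0] == 10

    def test_gap_mean_mode(self):
        assert global_average_pool(np.ones((1, 7, 7)), mode="mean")[0] == 1.0

    def test_class_scores_examples(self):
        np.testing.assert_allclose(class_scores([1, 2], np.eye(2)), [1, 2])
        np.testing.assert_allclose(class_scores([1, 2], np.zeros((2, 2))), [0, 0])
        W = np.array([[0.5, -0.5], [0.5, -0.5]])
        np.testing.assert_allclose(class_scores([1, 1], W), [1, -1])

    def test_class_scores_dimension_mismatch(self):
        with pytest.raises(ValueError):
            class_scores([1, 2, 3], np.eye(2))

    def test_softmax_pom_examples(self):
        p, pom = softmax_pom([0.0, 0.0], 1)
        np.testing.assert_allclose(p, [0.5, 0.5])
        assert pom == 0.5
        _, pom = softmax_pom([np.log(2), 0.0], 0)
        assert pom == pytest.approx(2 / 3)
        p1, _ = softmax_pom([1.0, 3.0], 1)
        p2, _ = softmax_pom([101.0, 103.0], 1)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_softmax_pom_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            softmax_pom([np.nan, 0.0], 1)


class TestForward:
    def test_zero_head_gives_uniform_probabilities(self):
        model = GapClassifier(TINY32).init_weights(0)
        model.head.w[...] = 0.0
        fwd = model.forward(np.random.default_rng(0).random((32, 32)))
        np.testing.assert_allclose(fwd.probabilities, [0.5, 0.5])

    def test_forward_self_consistency(self):
        model = GapClassifier(TINY32).init_weights(1)
        fwd = model.forward(np.random.default_rng(1).random((32, 32)))
        F = global_average_pool(fwd.feature_maps)
        S = class_scores(F, model.head_weights)
        np.testing.assert_allclose(S, fwd.class_scores, atol=1e-4)
        assert fwd.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
        assert 0.0 <= fwd.pom <= 1.0

    def test_batch_independence(self):
        model = GapClassifier(TINY32).init_weights(2)
        x = np.random.default_rng(2).random((1, 1, 32, 32)).astype(np.float32)
        out = model.forward_batch(np.concatenate([x, x]))
        np.testing.assert_allclose(out["pom"][0], out["pom"][1], atol=1e-7)

    def test_published_backbones_rejected(self):
        with pytest.raises(ValueError, match="vgg16"):
            GapClassifierConfig(backbone="vgg16")


class TestInit:
    def test_seeded_init_reproducible_and_seed_sensitive(self):
        m1 = GapClassifier(TINY32).init_weights(5)
        m2 = GapClassifier(TINY32).init_weights(5)
        m3 = GapClassifier(TINY32).init_weights(6)
        for p1, p2 in zip(m1.params, m2.params):
            np.testing.assert_array_equal(p1, p2)
        assert any(not np.array_equal(p1, p3)
                   for p1, p3 in zip(m1.params, m3.params))

    def test_he_variance(self):
        model = GapClassifier(GapClassifierConfig(input_side=32,
                                                  k_channels=64)).init_weights(7)
        conv = model.layers[-2]  # largest conv layer
        assert conv.w.var() == pytest.approx(2.0 / conv.fan_in, rel=0.1)


class TestTraining:
    def test_separable_phantoms_reach_high_tune_auc(self, easy64):
        _, images = easy64
        Xtr, ytr = split_arrays(images, "train")
        Xv, yv = split_arrays(images, "internal_val")
        model, log = train_classifier(
            Xtr, ytr, TrainingConfig(epochs=15, seed=0),
            GapClassifierConfig(input_side=64), Xv, yv)
        assert log["tune_auc"].max() >= 0.95

    def test_single_class_rejected(self):
        X = np.zeros((10, 32, 32), dtype=np.float32)
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(X, np.zeros(10, dtype=int), TrainingConfig(epochs=1),
                             TINY32)

    def test_large_weight_decay_shrinks_weights(self, easy64):
        _, images = easy64
        Xtr, ytr = split_arrays(images, "train")
        Xtr, ytr = Xtr[40:60], ytr[40:60]

        def norm_of(wd):
            model, _ = train_classifier(
                Xtr, ytr, TrainingConfig(epochs=2, weight_decay=wd, seed=3),
                GapClassifierConfig(input_side=64))
            return np.sqrt(sum(float((p ** 2).sum()) for p in model.params))

        assert norm_of(100.0) < norm_of(0.0)

    def test_empty_tune_falls_back_to_final_epoch(self, easy64):
        _, images = easy64
        Xtr, ytr = split_arrays(images, "train")
        _, log = train_classifier(Xtr[40:60], ytr[40:60],
                                  TrainingConfig(epochs=1, seed=0),
                                  GapClassifierConfig(input_side=64))
        assert "warning" in log.attrs

    def test_seeded_training_reproducible(self, easy64):
        _, images = easy64
        Xtr, ytr = split_arrays(images, "train")
        Xv, yv = split_arrays(images, "internal_val")
        args = (Xtr[40:60], ytr[40:60], TrainingConfig(epochs=2, seed=9),
                GapClassifierConfig(input_side=64), Xv, yv)
        _, log1 = train_classifier(*args)
        _, log2 = train_classifier(*args)
        assert log1["tune_auc"].tolist() == log2["tune_auc"].tolist()


class TestGridSearch:
    def test_single_point_grid_returns_it(self, easy64):
        _, images = easy64
        Xtr, ytr = split_arrays(images, "train")
        res = grid_search(Xtr[40:60], ytr[40:60],
                          {"learning_rate": [1e-3]},
                          TrainingConfig(epochs=1, seed=0),
                          GapClassifierConfig(input_side=64),
                          tune_per_class=3)
        assert res.best_config.learning_rate == 1e-3
        assert len(res.results) == 1

    def test_trained_config_beats_untrained(self, easy64):
        _, images = easy64
        Xtr, ytr = split_arrays(images, "train")
        res = grid_search(Xtr, ytr, {"epochs": [0, 10]},
                          TrainingConfig(seed=0),
                          GapClassifierConfig(input_side=64),
                          tune_per_class=10)
        assert res.best_config.epochs == 10

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search(np.zeros((4, 32, 32)), np.array([0, 1, 0, 1]), {})


class TestSegmenter:
    def test_probability_map_bounded_and_shaped(self):
        seg = UNetSegmenter(SegmenterConfig(base_channels=4,
                                            input_side=32)).init_weights(0)
        out = seg.segment(np.random.default_rng(0).random((32, 32)))
        assert out.prob_map.shape == (32, 32)
        assert out.prob_map.min() >= 0.0 and out.prob_map.max() <= 1.0
        assert out.mask.dtype == bool

    def test_empty_target_masks_rejected(self):
        X = np.random.default_rng(1).random((4, 32, 32)).astype(np.float32)
        M = np.zeros((4, 32, 32))
        M[:2, 10:20, 10:20] = 1
        with pytest.raises(ValueError, match="empty"):
            train_segmenter(X, M, SegmenterConfig(base_channels=4,
                                                  input_side=32, epochs=1))

    def test_save_load_roundtrip(self, tmp_path):
        seg = UNetSegmenter(SegmenterConfig(base_channels=4,
                                            input_side=32)).init_weights(3)
        seg.save(tmp_path / "seg")
        back = UNetSegmenter.load(tmp_path / "seg")
        x = np.random.default_rng(3).random((32, 32))
        np.testing.assert_allclose(back.segment(x).prob_map,
                                   seg.segment(x).prob_map)


def test_classifier_save_load_roundtrip(tmp_path):
    model = GapClassifier(TINY32).init_weights(4)
    model.save(tmp_path / "clf")
    back = GapClassifier.load(tmp_path / "clf")
    x = np.random.default_rng(4).random((32, 32))
    assert back.forward(x).pom == pytest.approx(model.forward(x).pom)
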