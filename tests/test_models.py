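"""Detectors: template matcher self-consistency, CNN training, AUC oracle."""

import numpy as np
import pytest

from camaudit.models import (
    TemplateDetector,
    equal_error_threshold,
    evaluate_model,
    mann_whitney_auc,
    template_detector,
    train_small_cnn,
)
from camaudit.synthetic import AnnotatedImage, DatasetSpec, generate_dataset


def trapezoidal_auc(scores, labels) -> float:
    """Oracle: trapezoidal integration of the empirical ROC curve."""
    thresholds = np.unique(scores)[::-1]
    pos = labels.sum()
    neg = (~labels).sum()
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        calls = scores >= t
        tpr.append((calls & labels).sum() / pos)
        fpr.append((calls & ~labels).sum() / neg)
    return float(np.trapezoid(tpr, fpr))


class TestTemplateDetector:
    def test_flat_image_scores_below_half(self, template_det):
        flat = AnnotatedImage(pixels=np.full((64, 64), 0.4), lesion_present=False)
        score, _ = template_det.score(flat)
        assert score < 0.5

    def test_predicted_box_tracks_true_lesion(self, template_det, lesion_images):
        """Self-consistency with the generator: the predicted box centre
        lands within one lesion radius of the true centre on >=90% of 50
        seeded lesion images."""
        hits = 0
        for img in lesion_images[:50]:
            _, box = template_det.score(img)
            r0, c0, r1, c1 = img.lesion_bbox
            br0, bc0, br1, bc1 = box
            dist = np.hypot(
                (br0 + br1 - r0 - r1) / 2, (bc0 + bc1 - c0 - c1) / 2
            )
            hits += dist <= template_det.lesion_radius
        assert hits >= 45

    def test_ablating_correlation_channel_collapses_score(
        self, template_det, lesion_images
    ):
        img = lesion_images[0]
        baseline, _ = template_det.score(img)
        ablated, _ = template_det.with_ablated_channel("features", 2).score(img)
        no_signal = 1.0 / (1.0 + np.exp(TemplateDetector.GAIN * TemplateDetector.MIDPOINT))
        assert baseline > 0.5
        assert ablated == pytest.approx(no_signal)

    def test_ablating_smoothing_channel_leaves_score(self, template_det, lesion_images):
        img = lesion_images[0]
        baseline, _ = template_det.score(img)
        ablated, _ = template_det.with_ablated_channel("features", 0).score(img)
        assert ablated == baseline

    def test_too_small_image_rejected(self, template_det):
        tiny = AnnotatedImage(pixels=np.zeros((8, 8)), lesion_present=False)
        with pytest.raises(ValueError, match="smaller"):
            template_det.score(tiny)

    def test_randomization_preserves_contract_not_weights(self, template_det):
        a = template_det.with_randomized_layers(["features"], seed=1)
        b = template_det.with_randomized_layers(["features"], seed=2)
        assert not np.array_equal(a.template, b.template)
        assert a.layer_names == template_det.layer_names
        # the original is untouched
        assert np.array_equal(
            template_det.template, template_detector(8).template
        )


class TestSmallCNN:
    def test_holdout_auc_on_separable_set(self, trained_cnn):
        held_out = generate_dataset(DatasetSpec(n_images=60, seed=22))
        result = evaluate_model(trained_cnn, held_out)
        assert result.auc >= 0.9

    def test_randomized_weights_fall_to_chance(self, trained_cnn):
        held_out = generate_dataset(DatasetSpec(n_images=60, seed=23))
        wrecked = trained_cnn.with_randomized_layers(
            list(trained_cnn.layer_names), seed=5
        )
        result = evaluate_model(wrecked, held_out)
        # binomial 95% band around chance at n=60
        assert abs(result.accuracy - 0.5) <= 2 * np.sqrt(0.25 / 60) + 1e-9

    def test_training_is_deterministic(self, train_set, trained_cnn):
        again = train_small_cnn(train_set, epochs=50, seed=3)
        for name in trained_cnn.weights:
            np.testing.assert_array_equal(
                trained_cnn.weights[name], again.weights[name]
            )
        np.testing.assert_array_equal(trained_cnn.head_w, again.head_w)

    def test_single_class_dataset_rejected(self):
        ds = generate_dataset(
            DatasetSpec(n_images=4, lesion_fraction=0.0, seed=1)
        )
        with pytest.raises(ValueError, match="both classes"):
            train_small_cnn(ds, epochs=1)

    def test_ablation_fast_path_matches_contract_route(
        self, trained_cnn, study_dataset
    ):
        img = study_dataset[0]
        acts = trained_cnn.activations(img, "conv3")
        for ch in (0, 5):
            ablated = acts.copy()
            ablated[ch] = 0.0
            fast = trained_cnn.score_from_activations(img, "conv3", ablated)
            slow = trained_cnn.with_ablated_channel("conv3", ch).score(img)[0]
            assert fast == pytest.approx(slow, abs=1e-12)


class TestEvaluateModel:
    def test_perfect_separation_gives_auc_one(self, study_dataset):
        class Oracle:
            layer_names = ()
            cam_layer = ""
            def score(self, img):
                return (1.0 if img.lesion_present else 0.0), None
        result = evaluate_model(Oracle(), study_dataset[:20])
        assert result.auc == 1.0 and result.accuracy == 1.0

    def test_label_independent_scores_give_half_auc(self):
        """Permutation Monte-Carlo: random scores hover around AUC 0.5."""
        rng = np.random.default_rng(9)
        labels = np.array([True] * 50 + [False] * 50)
        aucs = [
            mann_whitney_auc(rng.random(100), labels) for _ in range(200)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_rank_auc_matches_trapezoidal_on_random_sets(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(10, 50))
            scores = np.round(rng.random(n), 2)  # ties included
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert mann_whitney_auc(scores, labels) == pytest.approx(
                trapezoidal_auc(scores, labels)
            )

    def test_one_class_dataset_flagged(self):
        ds = generate_dataset(DatasetSpec(n_images=3, lesion_fraction=0.0, seed=4))
        det = template_detector(8)
        result = evaluate_model(det, ds)
        assert result.auc is None

    def test_equal_error_threshold_separates_separable_scores(self):
        scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9, 0.95])
        labels = np.array([False, False, False, True, True, True])
        t = equal_error_threshold(scores, labels)
        assert 0.3 < t <= 0.8
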