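"""CAM explainers against closed-form and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camaudit.cams import (
    AblationCAM,
    ConstantExplainer,
    EigenCAM,
    GroundTruthExplainer,
)
from camaudit.synthetic import AnnotatedImage


def make_image(side=8):
    return AnnotatedImage(pixels=np.full((side, side), 0.4), lesion_present=False)


def minmax(x):
    lo, hi = x.min(), x.max()
    return (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)


class TestEigenCAM:
    def test_all_zero_activations_degenerate(self, static_model_factory):
        model = static_model_factory(np.zeros((3, 8, 8)))
        h = EigenCAM()(model, make_image())
        assert h.degenerate and not h.values.any()

    @pytest.mark.parametrize("weights", [(1.0, 2.0, 3.0), (-1.0, 0.5, 2.0)])
    def test_rank_one_stack_recovers_base_pattern(
        self, static_model_factory, weights
    ):
        """For activations A_c = w_c * M (M >= 0) the heatmap equals the
        min-max-normalized M for any channel weights (checked against a
        brute-force SVD of the 3x4x4 stack)."""
        rng = np.random.default_rng(0)
        base = rng.random((4, 4))
        acts = np.stack([w * base for w in weights])
        # independent oracle: full SVD of the flattened matrix
        _, _, vt = np.linalg.svd(acts.reshape(3, 16))
        oracle = np.abs(vt[0]).reshape(4, 4)  # rank one => sign-flip of M
        np.testing.assert_allclose(minmax(oracle), minmax(base), atol=1e-12)

        model = static_model_factory(acts)
        h = EigenCAM()(model, make_image(4))
        np.testing.assert_allclose(h.values, minmax(base), atol=1e-9)

    def test_single_nonzero_channel_recovers_pattern(self, static_model_factory):
        rng = np.random.default_rng(1)
        pattern = rng.random((4, 4))
        acts = np.zeros((3, 4, 4))
        acts[1] = pattern
        model = static_model_factory(acts)
        h = EigenCAM()(model, make_image(4))
        np.testing.assert_allclose(h.values, minmax(pattern), atol=1e-9)

    def test_invariant_to_positive_rescaling(self, static_model_factory):
        rng = np.random.default_rng(2)
        acts = rng.random((3, 6, 6))
        img = make_image(6)
        a = EigenCAM()(static_model_factory(acts), img)
        b = EigenCAM()(static_model_factory(7.5 * acts), img)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_upsamples_to_input_resolution(self, static_model_factory):
        acts = np.random.default_rng(3).random((2, 4, 4))
        h = EigenCAM()(static_model_factory(acts), make_image(16))
        assert h.values.shape == (16, 16)


class TestAblationCAM:
    def test_score_independent_of_layer_gives_degenerate_map(
        self, static_model_factory
    ):
        model = static_model_factory(
            np.random.default_rng(4).random((3, 4, 4)), coefs=[0, 0, 0]
        )
        h = AblationCAM()(model, make_image(4))
        assert h.degenerate and not h.values.any()

    def test_linear_model_weights_match_closed_form(self, static_model_factory):
        """For y = sum_c a_c mean(A_c), ablating channel c drops the score by
        a_c mean(A_c), so w_c = a_c mean(A_c) / y exactly."""
        rng = np.random.default_rng(5)
        acts = rng.random((3, 4, 4))
        coefs = np.array([0.5, 2.0, -0.3])
        model = static_model_factory(acts, coefs=coefs)
        y = float(coefs @ acts.mean(axis=(1, 2)))
        expected = coefs * acts.mean(axis=(1, 2)) / y
        got = AblationCAM().channel_weights(model, make_image(4), "feat")
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_single_contributing_channel(self, static_model_factory):
        rng = np.random.default_rng(6)
        acts = rng.random((3, 4, 4))
        model = static_model_factory(acts, coefs=[0.0, 1.0, 0.0])
        weights = AblationCAM().channel_weights(model, make_image(4), "feat")
        np.testing.assert_allclose(weights, [0.0, 1.0, 0.0], atol=1e-12)
        h = AblationCAM()(model, make_image(4))
        np.testing.assert_allclose(h.values, minmax(acts[1]), atol=1e-9)

    def test_weights_invariant_to_score_rescaling(self, static_model_factory):
        rng = np.random.default_rng(7)
        acts = rng.random((3, 4, 4))
        img = make_image(4)
        w1 = AblationCAM().channel_weights(
            static_model_factory(acts, coefs=[1.0, 2.0, 3.0]), img, "feat"
        )
        w2 = AblationCAM().channel_weights(
            static_model_factory(acts, coefs=[10.0, 20.0, 30.0]), img, "feat"
        )
        np.testing.assert_allclose(w1, w2, atol=1e-12)

    def test_zero_baseline_score_reported_degenerate(self, static_model_factory):
        model = static_model_factory(np.zeros((2, 4, 4)), coefs=[1.0, 1.0])
        h = AblationCAM()(model, make_image(4))
        assert h.degenerate


class TestExplainerContract:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_output_normalization_invariant(self, seed, static_model_factory):
        """Non-constant maps span [0, 1] exactly; constant raw maps are all
        zeros and flagged degenerate."""
        rng = np.random.default_rng(seed)
        acts = rng.random((3, 5, 5))
        model = static_model_factory(acts, coefs=rng.random(3))
        img = make_image(10)
        for explainer in (EigenCAM(), AblationCAM()):
            h = explainer(model, img)
            assert np.all(np.isfinite(h.values))
            if h.degenerate:
                assert not h.values.any()
            else:
                assert h.values.min() == 0.0
                assert h.values.max() == pytest.approx(1.0)

    def test_deterministic_given_model_and_input(self, template_det, study_dataset):
        img = study_dataset[0]
        for explainer in (EigenCAM(), AblationCAM()):
            a = explainer(template_det, img)
            b = explainer(template_det, img)
            np.testing.assert_array_equal(a.values, b.values)

    def test_ground_truth_oracle_marks_the_lesion_box(self, lesion_images):
        img = lesion_images[0]
        h = GroundTruthExplainer()(None, img)
        r0, c0, r1, c1 = img.lesion_bbox
        assert h.values[r0:r1, c0:c1].all()
        assert h.values.sum() == (r1 - r0) * (c1 - c0)

    def test_constant_explainer_ignores_the_model(self, template_det, study_dataset):
        ex = ConstantExplainer()
        a = ex(template_det, study_dataset[0])
        b = ex(template_det.with_randomized_layers(["features"], 1), study_dataset[0])
        np.testing.assert_array_equal(a.values, b.values)
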