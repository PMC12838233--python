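"""Fidelity checks: randomization, deletions, white-box, control arms."""

import numpy as np
import pytest

from camaudit.cams import AblationCAM, ConstantExplainer, EigenCAM, Heatmap
from camaudit.fidelity import (
    incremental_deletion,
    masked_roi_deletion,
    random_mask_score_changes,
    randomization_check,
    white_box_check,
)
from camaudit.metrics import box_iou, roi_from_heatmap


class SelfExplainer:
    """Returns the template detector's own correlation map (positive part)."""

    name = "self_correlation"

    def __call__(self, model, image):
        corr = model.activations(image, "features")[-1]
        corr = np.maximum(corr, 0.0)
        hi = corr.max()
        values = corr / hi if hi > 0 else corr
        return Heatmap(values, "features", self.name)


class TestRandomizationCheck:
    def test_constant_explainer_flagged_low_fidelity(
        self, template_det, subset30
    ):
        records = randomization_check(
            template_det, ConstantExplainer(), subset30[:8],
            layers=["features"], seed=1,
        )
        randomized = [r for r in records if r.check == "randomization"][0]
        assert all(r["ssim"] == 1.0 for r in randomized.per_image)
        assert any("low_fidelity" in f for f in randomized.flags)

    def test_control_arm_is_perfect(self, template_det, subset30):
        records = randomization_check(
            template_det, AblationCAM(), subset30[:8],
            layers=["features"], seed=2,
        )
        control = records[0]
        assert control.check == "randomization_control"
        assert all(r["ssim"] == 1.0 for r in control.per_image)
        assert control.accuracy_pre == control.accuracy_post
        assert control.score_change == 0.0

    def test_modes_produce_expected_arm_counts(self, template_det, subset30):
        few = subset30[:4]
        ind = randomization_check(
            template_det, AblationCAM(), few, ["smooth", "features"], mode="independent"
        )
        cas = randomization_check(
            template_det, AblationCAM(), few, ["smooth", "features"], mode="cascade"
        )
        joint = randomization_check(
            template_det, AblationCAM(), few, ["smooth", "features"], mode="joint"
        )
        assert len(ind) == 3 and len(cas) == 3 and len(joint) == 2
        assert cas[-1].params["layers"] == ["features", "smooth"]

    def test_empty_layer_list_rejected(self, template_det, subset30):
        with pytest.raises(ValueError):
            randomization_check(template_det, AblationCAM(), subset30[:2], [])

    def test_record_names_intervention_parameters(self, template_det, subset30):
        records = randomization_check(
            template_det, AblationCAM(), subset30[:2], ["features"], seed=9
        )
        for record in records:
            assert "layers" in record.params and "seed" in record.params
            assert record.accuracy_pre is not None
            assert record.accuracy_post is not None


class TestMaskedRoiDeletion:
    def test_masking_the_lesion_peak_drops_the_score(
        self, template_det, lesion_images
    ):
        """A faithful heatmap peaks on the lesion; masking that ROI removes
        the matched filter's correlation target."""
        drops = 0
        for img in lesion_images[:10]:
            record = masked_roi_deletion(template_det, AblationCAM(), img)
            if record.score_change < 0 and record.accuracy_post == 0.0:
                drops += 1
        assert drops >= 8

    def test_background_masking_dissociates_from_lesion_masking(
        self, template_det, study_dataset
    ):
        """Off-peak regions carry no signal (random masks barely move the
        score), and masking the heatmap peak on lesion-absent images changes
        the score far less than masking a true lesion — and never flips a
        correct negative call."""
        absent = [i for i in study_dataset if not i.lesion_present][:5]
        present = [i for i in study_dataset if i.lesion_present][:5]
        # Monte-Carlo control: most random masks miss the peak entirely
        control = np.concatenate(
            [
                random_mask_score_changes(
                    template_det, img, roi_size=(17, 17), n=20, seed=3
                )
                for img in absent
            ]
        )
        assert np.median(np.abs(control)) < 0.01

        absent_drops = []
        for img in absent:
            record = masked_roi_deletion(
                template_det, AblationCAM(), img, roi_size=(17, 17)
            )
            absent_drops.append(abs(record.score_change))
            assert record.accuracy_post == 1.0  # negative call unchanged
        lesion_drops = [
            abs(
                masked_roi_deletion(
                    template_det, AblationCAM(), img, roi_size=(17, 17)
                ).score_change
            )
            for img in present
        ]
        assert np.mean(absent_drops) < np.mean(lesion_drops)

    def test_degenerate_heatmap_skips_deletion(self, template_det, study_dataset):
        class ZeroExplainer:
            name = "zero"
            def __call__(self, model, image):
                return Heatmap(
                    np.zeros(image.shape), "none", "zero", degenerate=True
                )
        record = masked_roi_deletion(
            template_det, ZeroExplainer(), study_dataset[0]
        )
        assert record.flags and record.accuracy_post is None


class TestIncrementalDeletion:
    def test_zero_steps_returns_baseline_only(self, template_det, lesion_images):
        curve = incremental_deletion(
            template_det, AblationCAM(), lesion_images[0], (16, 16), 0
        )
        assert len(curve.scores) == 1
        assert curve.area == curve.scores[0]

    def test_importance_order_hurts_more_than_reverse(
        self, template_det, lesion_images
    ):
        """Deleting claimed-important regions first suppresses the score
        curve; deleting least-important first spares it (paired over 10
        images)."""
        diffs = []
        for img in lesion_images[:10]:
            imp = incremental_deletion(
                template_det, AblationCAM(), img, (16, 16), 5, order="importance"
            )
            rev = incremental_deletion(
                template_det, AblationCAM(), img, (16, 16), 5, order="reverse"
            )
            diffs.append(rev.area - imp.area)
        assert np.mean(diffs) > 0
        assert sum(d >= 0 for d in diffs) >= 8

    def test_boxes_never_overlap(self, template_det, lesion_images):
        curve = incremental_deletion(
            template_det, AblationCAM(), lesion_images[1], (16, 16), 6
        )
        seen = np.zeros(lesion_images[1].shape, dtype=bool)
        for r0, c0, r1, c1 in curve.boxes:
            assert not seen[r0:r1, c0:c1].any()
            seen[r0:r1, c0:c1] = True

    def test_area_budget_precondition(self, template_det, lesion_images):
        with pytest.raises(ValueError, match="area"):
            incremental_deletion(
                template_det, AblationCAM(), lesion_images[0], (64, 64), 5
            )

    def test_exhaustion_truncates_with_flag(self, template_det, lesion_images):
        # at most four disjoint 48x48 boxes fit in a 128x128 frame, so a
        # 7-step request must truncate even though the area budget allows it
        curve = incremental_deletion(
            template_det, AblationCAM(), lesion_images[0], (48, 48), 7
        )
        assert curve.truncated
        assert len(curve.boxes) <= 4


class TestWhiteBoxCheck:
    def test_self_explanation_is_perfect(self, subset30):
        record = white_box_check(SelfExplainer(), subset30[:10], lesion_radius=8)
        assert record.summary["iou"]["mean"] == 1.0

    def test_constant_explainer_at_chance_overlap(self, template_det, subset30):
        """A constant map always yields the same fixed (centred) ROI; its
        mean IoU equals the geometric overlap of that box with the
        detector's boxes, computed here by brute force."""
        subset = subset30[:10]
        record = white_box_check(
            ConstantExplainer(), subset, lesion_radius=8
        )
        side = 2 * 8
        h = subset[0].shape[0]
        start = int(np.floor((h - 1) / 2 - (side - 1) / 2 + 0.5))
        fixed = (start, start, start + side, start + side)
        expected = []
        for img in subset:
            _, box = template_det.score(img)
            expected.append(box_iou(fixed, box))
        assert record.summary["iou"]["mean"] == pytest.approx(np.mean(expected))

    def test_both_cams_reported_descriptively(self, subset30):
        few = subset30[:6]
        eig = white_box_check(EigenCAM(), few, lesion_radius=8)
        abl = white_box_check(AblationCAM(), few, lesion_radius=8)
        for record in (eig, abl):
            assert 0.0 <= record.summary["iou"]["mean"] <= 1.0
            assert record.accuracy_pre is not None
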