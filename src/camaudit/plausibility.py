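"""Criterion 2 — plausibility: agreement with ground-truth lesion locations.

For every lesion-present image the heatmap's highest-activation ROI (a box
centred on the heatmap peak) is compared with the true lesion box by IoU.
Lesion-absent images cannot be scored this way and contribute only to the
co-reported model accuracy; IoU and accuracy are reported side by side and
never blended into a single scalar.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from ._stats import sign_flip_test
from .cams import Explainer
from .metrics import box_iou, roi_from_heatmap
from .models import DetectionModel
from .results import CriterionResult, accuracy_by_condition, summarize_records
from .synthetic import AnnotatedImage


def evaluate_plausibility(
    model: DetectionModel,
    explainer: Explainer,
    dataset: Sequence[AnnotatedImage],
    roi_size: Optional[tuple[int, int]] = None,
    threshold: float = 0.5,
    seed: int = 0,
) -> CriterionResult:
    """Mean ROI-vs-ground-truth IoU over lesion-present images.

    ``roi_size`` defaults to each image's own ground-truth box size, so a
    perfect explanation attains IoU 1 exactly. Raises if the dataset has no
    lesion-present image (plausibility is undefined without ground truth).
    """
    if not any(img.lesion_present for img in dataset):
        raise ValueError("plausibility requires lesion-present images")

    records: list[dict] = []
    for idx, img in enumerate(dataset):
        score, _ = model.score(img)
        correct = bool((score >= threshold) == img.lesion_present)
        if not img.lesion_present:
            records.append(
                {
                    "image_id": idx,
                    "condition": "lesion_absent",
                    "iou": None,
                    "model_correct": correct,
                }
            )
            continue
        heatmap = explainer(model, img)
        bbox = img.lesion_bbox
        size = roi_size or (bbox[2] - bbox[0], bbox[3] - bbox[1])
        roi = roi_from_heatmap(heatmap, size)
        records.append(
            {
                "image_id": idx,
                "condition": "lesion_present",
                "iou": box_iou(roi.box, bbox),
                "model_correct": correct,
            }
        )

    accuracy = accuracy_by_condition(records)
    accuracy["overall"] = float(np.mean([r["model_correct"] for r in records]))
    return CriterionResult(
        criterion="plausibility",
        per_image=records,
        summary=summarize_records(records, seed=seed),
        model_accuracy=accuracy,
    )


def compare_explainers(
    result_a: CriterionResult,
    result_b: CriterionResult,
    n_perm: int = 10000,
    seed: int = 0,
) -> dict:
    """Paired comparison of two plausibility results on the same dataset.

    Tests whether explainer A's per-image IoU exceeds explainer B's with a
    one-sided sign-flip permutation test on the paired differences.
    """
    a = {r["image_id"]: r["iou"] for r in result_a.per_image if r["iou"] is not None}
    b = {r["image_id"]: r["iou"] for r in result_b.per_image if r["iou"] is not None}
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("results share no lesion-present images")
    diffs = np.array([a[i] - b[i] for i in shared])
    return {
        "n_pairs": len(shared),
        "mean_iou_a": float(np.mean([a[i] for i in shared])),
        "mean_iou_b": float(np.mean([b[i] for i in shared])),
        "mean_difference": float(diffs.mean()),
        "p_value": sign_flip_test(diffs, n_perm=n_perm, seed=seed,
                                  alternative="greater"),
    }
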