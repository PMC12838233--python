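"""Criterion 3 — fidelity: does the explanation track the model's mechanism?

Four checks probe the link between heatmaps and the model's actual decision
path:

* weight-randomization — re-initialize layers and compare explanations
  before/after; an explanation that survives randomization cannot be
  reflecting the weights;
* masked-ROI (single) deletion — remove the highest-activation region from
  the input and re-score;
* incremental deletion — remove regions in (or against) claimed importance
  order and follow the score curve;
* white-box check — compare the explainer's ROI against the evidence region
  of a transparent matched-filter detector.

Every record carries both the explanation-similarity change and the model
accuracy around the intervention: either quantity alone is ambiguous (an
explanation can change while the model is unaffected, and vice versa), so
the record structure does not allow emitting one without the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cams import Explainer
from .metrics import box_iou, compare_heatmaps, roi_from_heatmap
from .models import DetectionModel, TemplateDetector, template_detector
from .results import summarize_records
from .synthetic import BACKGROUND_MEAN, AnnotatedImage

#: mean pre/post SSIM at or above which explanations are considered
#: unchanged by an intervention (=> low fidelity for randomization)
UNCHANGED_SSIM = 0.99


@dataclass
class FidelityRecord:
    """Outcome of one fidelity intervention.

    ``params`` names the intervention's parameters (layers, ROI size, fill
    rule, seed); ``per_image`` holds tidy pre/post similarity records;
    ``summary`` aggregates them; accuracy (or per-image correctness) before
    and after the intervention is always present alongside the similarity.
    """

    check: str
    params: dict
    per_image: list[dict]
    summary: dict
    accuracy_pre: Optional[float]
    accuracy_post: Optional[float]
    score_change: Optional[float] = None
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class DeletionCurve:
    """Model score as regions are removed step by step.

    ``scores[0]`` is the baseline; ``area`` is the mean of the post-step
    scores (step-count-invariant denominator). ``truncated`` marks curves
    stopped early because no further non-overlapping region fit.
    """

    order: str
    scores: tuple[float, ...]
    boxes: tuple[tuple[int, int, int, int], ...]
    truncated: bool = False

    @property
    def area(self) -> float:
        if len(self.scores) < 2:
            return float(self.scores[0])
        return float(np.mean(self.scores[1:]))


def _correct(score: float, img: AnnotatedImage, threshold: float) -> bool:
    return bool((score >= threshold) == img.lesion_present)


# --------------------------------------------------------------------------
# model parameter randomization check


def randomization_check(
    model: DetectionModel,
    explainer: Explainer,
    dataset: Sequence[AnnotatedImage],
    layers: Sequence[str],
    seed: int = 0,
    mode: str = "independent",
    threshold: float = 0.5,
    include_control: bool = True,
) -> list[FidelityRecord]:
    """Explanations and accuracy before vs after weight re-initialization.

    ``mode='independent'`` randomizes each named layer alone (one record per
    layer); ``'cascade'`` randomizes cumulatively from the last named layer
    backwards; ``'joint'`` randomizes all named layers at once. A control
    record (re-explaining the unchanged model) is emitted first: it must
    show perfect similarity and unchanged accuracy, and anchors what "no
    intervention" looks like. Explanations that stay unchanged under actual
    randomization are flagged low-fidelity.
    """
    layers = list(layers)
    if not layers:
        raise ValueError("layers must be non-empty")
    unknown = set(layers) - set(model.layer_names)
    if unknown:
        raise ValueError(f"unknown layers: {sorted(unknown)}")

    if mode == "independent":
        layer_sets = [[lay] for lay in layers]
    elif mode == "cascade":
        rev = layers[::-1]
        layer_sets = [rev[: i + 1] for i in range(len(rev))]
    elif mode == "joint":
        layer_sets = [layers]
    else:
        raise ValueError(f"unknown mode: {mode!r}")

    reference = [explainer(model, img) for img in dataset]
    scores_pre = np.array([model.score(img)[0] for img in dataset])
    acc_pre = float(
        np.mean([_correct(s, i, threshold) for s, i in zip(scores_pre, dataset)])
    )

    records = []
    arms = ([("control", None)] if include_control else []) + [
        ("randomized", ls) for ls in layer_sets
    ]
    for arm, layer_set in arms:
        if layer_set is None:
            probe = model
        else:
            probe = model.with_randomized_layers(layer_set, seed=seed)
        per_image = []
        scores_post = []
        for idx, img in enumerate(dataset):
            explained = explainer(probe, img)
            bundle = compare_heatmaps(reference[idx].values, explained.values)
            s_post, _ = probe.score(img)
            scores_post.append(s_post)
            per_image.append(
                {
                    "image_id": idx,
                    "condition": arm,
                    "ssim": bundle.ssim,
                    "mse": bundle.mse,
                    "iou": bundle.iou,
                    "model_correct": _correct(s_post, img, threshold),
                }
            )
        summary = summarize_records(per_image, seed=seed)[arm]
        acc_post = float(
            np.mean(
                [_correct(s, i, threshold) for s, i in zip(scores_post, dataset)]
            )
        )
        flags = []
        if arm == "randomized" and summary["ssim"]["mean"] >= UNCHANGED_SSIM:
            flags.append(
                "low_fidelity: explanations unchanged under weight randomization"
            )
        records.append(
            FidelityRecord(
                check="randomization" if arm == "randomized" else
                      "randomization_control",
                params={"layers": layer_set or [], "seed": seed, "mode": mode},
                per_image=per_image,
                summary=summary,
                accuracy_pre=acc_pre,
                accuracy_post=acc_post,
                score_change=float(np.mean(np.array(scores_post) - scores_pre)),
                flags=flags,
            )
        )
    return records


# --------------------------------------------------------------------------
# input deletion checks


def _mask_box(
    px: np.ndarray, box: tuple[int, int, int, int], fill: float
) -> np.ndarray:
    out = px.copy()
    r0, c0, r1, c1 = box
    out[r0:r1, c0:c1] = fill
    return out


def _default_roi_size(
    img: AnnotatedImage, roi_size: Optional[tuple[int, int]]
) -> tuple[int, int]:
    if roi_size is not None:
        return roi_size
    if img.lesion_bbox is not None:
        r0, c0, r1, c1 = img.lesion_bbox
        return (r1 - r0, c1 - c0)
    side = max(img.shape[0] // 8, 1)
    return (side, side)


def masked_roi_deletion(
    model: DetectionModel,
    explainer: Explainer,
    image: AnnotatedImage,
    roi_size: Optional[tuple[int, int]] = None,
    fill: float = BACKGROUND_MEAN,
    threshold: float = 0.5,
) -> FidelityRecord:
    """Single deletion: remove the highest-activation ROI and re-run.

    The ROI (defaulting to the ground-truth box size) is replaced by the
    fill level; the record holds the score change and the pre/post heatmap
    similarity. A degenerate all-zero heatmap has no peak, so no deletion is
    performed and the record is flagged.
    """
    from dataclasses import replace as _dc_replace

    heatmap = explainer(model, image)
    score_pre, _ = model.score(image)
    params = {"roi_size": roi_size, "fill": fill}
    if heatmap.degenerate and not heatmap.values.any():
        return FidelityRecord(
            check="masked_roi",
            params=params,
            per_image=[],
            summary={},
            accuracy_pre=float(_correct(score_pre, image, threshold)),
            accuracy_post=None,
            flags=["degenerate: all-zero heatmap, deletion skipped"],
        )
    size = _default_roi_size(image, roi_size)
    roi = roi_from_heatmap(heatmap, size)
    masked = _dc_replace(image, pixels=_mask_box(image.pixels, roi.box, fill))
    score_post, _ = model.score(masked)
    explained_post = explainer(model, masked)
    bundle = compare_heatmaps(heatmap.values, explained_post.values)
    record = {
        "image_id": 0,
        "condition": "masked_roi",
        "ssim": bundle.ssim,
        "mse": bundle.mse,
        "iou": bundle.iou,
        "model_correct": _correct(score_post, image, threshold),
    }
    return FidelityRecord(
        check="masked_roi",
        params={**params, "roi_box": roi.box},
        per_image=[record],
        summary={"ssim": bundle.ssim, "mse": bundle.mse, "iou": bundle.iou},
        accuracy_pre=float(_correct(score_pre, image, threshold)),
        accuracy_post=float(_correct(score_post, image, threshold)),
        score_change=float(score_post - score_pre),
    )


def random_mask_score_changes(
    model: DetectionModel,
    image: AnnotatedImage,
    roi_size: Optional[tuple[int, int]] = None,
    n: int = 50,
    seed: int = 0,
    fill: float = BACKGROUND_MEAN,
) -> np.ndarray:
    """Monte-Carlo control: score changes from randomly placed ROI masks."""
    from dataclasses import replace as _dc_replace

    size = _default_roi_size(image, roi_size)
    h, w = image.shape
    rng = np.random.default_rng(seed)
    score_pre, _ = model.score(image)
    deltas = np.empty(n)
    for k in range(n):
        r0 = int(rng.integers(0, h - size[0] + 1))
        c0 = int(rng.integers(0, w - size[1] + 1))
        box = (r0, c0, r0 + size[0], c0 + size[1])
        masked = _dc_replace(image, pixels=_mask_box(image.pixels, box, fill))
        deltas[k] = model.score(masked)[0] - score_pre
    return deltas


def incremental_deletion(
    model: DetectionModel,
    explainer: Explainer,
    image: AnnotatedImage,
    step_roi: tuple[int, int],
    n_steps: int,
    order: str = "importance",
    seed: int = 0,
    fill: float = BACKGROUND_MEAN,
) -> DeletionCurve:
    """Delete non-overlapping regions step by step and track the score.

    The ranking comes from the explanation of the *original* image:
    ``order='importance'`` deletes around the highest remaining heatmap
    values first, ``'reverse'`` around the lowest, ``'random'`` picks seeded
    random positions. Each step's box may not overlap previously deleted
    pixels; if no admissible box remains the curve is truncated and flagged.
    """
    if order not in ("importance", "reverse", "random"):
        raise ValueError(f"unknown order: {order!r}")
    sh, sw = step_roi
    h, w = image.shape
    if n_steps * sh * sw > h * w:
        raise ValueError("total deletion area exceeds the image area")
    from dataclasses import replace as _dc_replace

    heatmap = explainer(model, image)
    values = heatmap.values
    deleted = np.zeros(image.shape, dtype=bool)
    px = image.pixels.copy()
    scores = [model.score(image)[0]]
    boxes: list[tuple[int, int, int, int]] = []
    rng = np.random.default_rng(seed)
    truncated = False

    for _ in range(int(n_steps)):
        box = _next_box(values, deleted, (sh, sw), order, rng)
        if box is None:
            truncated = True
            break
        r0, c0, r1, c1 = box
        px[r0:r1, c0:c1] = fill
        deleted[r0:r1, c0:c1] = True
        boxes.append(box)
        scores.append(model.score(_dc_replace(image, pixels=px))[0])

    return DeletionCurve(
        order=order,
        scores=tuple(scores),
        boxes=tuple(boxes),
        truncated=truncated,
    )


_MAX_PLACEMENT_TRIES = 2000


def _next_box(
    values: np.ndarray,
    deleted: np.ndarray,
    size: tuple[int, int],
    order: str,
    rng: np.random.Generator,
) -> Optional[tuple[int, int, int, int]]:
    """Next admissible (non-overlapping) box centred on the best remaining
    pixel for the given order."""
    h, w = values.shape
    sh, sw = size
    available = ~deleted
    if order == "random":
        candidates = np.flatnonzero(available)
        if candidates.size == 0:
            return None
        candidates = rng.permutation(candidates)[:_MAX_PLACEMENT_TRIES]
    else:
        masked = np.where(available, values, -np.inf if order == "importance" else np.inf)
        flat = masked.ravel()
        if order == "importance":
            candidates = np.argsort(-flat, kind="stable")
        else:
            candidates = np.argsort(flat, kind="stable")
        candidates = candidates[np.isfinite(flat[candidates])][:_MAX_PLACEMENT_TRIES]
    for flat_idx in candidates:
        pr, pc = divmod(int(flat_idx), w)
        r0 = int(np.clip(pr - sh // 2, 0, h - sh))
        c0 = int(np.clip(pc - sw // 2, 0, w - sw))
        if not deleted[r0 : r0 + sh, c0 : c0 + sw].any():
            return (r0, c0, r0 + sh, c0 + sw)
    return None


# --------------------------------------------------------------------------
# white box check


def white_box_check(
    explainer: Explainer,
    dataset: Sequence[AnnotatedImage],
    lesion_radius: Optional[int] = None,
    detector: Optional[TemplateDetector] = None,
    threshold: float = 0.5,
    seed: int = 0,
) -> FidelityRecord:
    """Compare explainer ROIs against a transparent detector's own evidence.

    The matched-filter detector's predicted box marks the correlation peak —
    the region its decision provably rests on. Per image, the IoU between
    the explainer's highest-activation ROI (same box size) and that evidence
    box measures how faithfully the explainer recovers a known mechanism.
    """
    if detector is None:
        if lesion_radius is None:
            lesion_radius = _radius_from_dataset(dataset)
        detector = template_detector(lesion_radius)
    r = detector.lesion_radius
    per_image = []
    for idx, img in enumerate(dataset):
        score, evidence_box = detector.score(img)
        heatmap = explainer(detector, img)
        size = (evidence_box[2] - evidence_box[0], evidence_box[3] - evidence_box[1])
        roi = roi_from_heatmap(heatmap, size)
        per_image.append(
            {
                "image_id": idx,
                "condition": "white_box",
                "iou": box_iou(roi.box, evidence_box),
                "model_correct": _correct(score, img, threshold),
            }
        )
    summary = summarize_records(per_image, seed=seed)["white_box"]
    acc = float(np.mean([r_["model_correct"] for r_ in per_image]))
    return FidelityRecord(
        check="white_box",
        params={"lesion_radius": r},
        per_image=per_image,
        summary=summary,
        accuracy_pre=acc,
        accuracy_post=acc,
    )


def _radius_from_dataset(dataset: Sequence[AnnotatedImage]) -> int:
    sizes = [
        img.lesion_bbox[2] - img.lesion_bbox[0]
        for img in dataset
        if img.lesion_bbox is not None
    ]
    if not sizes:
        raise ValueError("cannot infer lesion radius from a dataset without lesions")
    return max(int(np.median(sizes)) // 2, 1)
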