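"""Criterion 1 — consistency: explanation stability under input perturbation.

For each image the reference heatmap (unperturbed input) is compared with
the heatmap of the perturbed input at every level of every perturbation.
Rotated heatmaps are realigned to the original frame first and all metrics
are restricted to the pixels that survived the rotation round trip. Model
correctness is co-reported at every level so that the characteristic
dissociation — metrics fluctuating while accuracy stays flat — is visible
rather than hidden in an average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cams import Explainer
from .metrics import compare_heatmaps
from .models import DetectionModel
from .results import CriterionResult, accuracy_by_condition, summarize_records
from .synthetic import AnnotatedImage, inverse_rotate, perturb

#: fraction of degenerate (all-zero) explanations above which the
#: criterion result is flagged unreliable
DEGENERATE_FLAG_FRACTION = 0.5

#: default perturbation grids; dose factor 1 / angle 0 are identity levels
DEFAULT_DOSE_LEVELS = (1.0, 0.66, 0.5, 0.33)
DEFAULT_ROTATION_ANGLES = (0.0, 10.0, 25.0, 50.0)


@dataclass(frozen=True)
class PerturbationSpec:
    """One family of input perturbations applied at several levels."""

    kind: str  # 'dose' or 'rotation'
    levels: tuple[float, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("dose", "rotation"):
            raise ValueError(f"unknown perturbation kind: {self.kind!r}")
        if not self.levels:
            raise ValueError("levels must be non-empty")
        if self.kind == "dose" and any(v <= 0 for v in self.levels):
            raise ValueError("dose levels must be positive")
        if self.kind == "rotation" and any(
            abs(_wrap_angle(a)) > 180 for a in self.levels
        ):
            raise ValueError("rotation angles must satisfy |angle| <= 180")


def _wrap_angle(a: float) -> float:
    a = a % 360.0
    return a - 360.0 if a > 180.0 else a


def default_perturbations(seed: int = 0) -> list[PerturbationSpec]:
    return [
        PerturbationSpec("dose", DEFAULT_DOSE_LEVELS, seed=seed),
        PerturbationSpec("rotation", DEFAULT_ROTATION_ANGLES, seed=seed),
    ]


def _is_identity(kind: str, level: float) -> bool:
    if kind == "dose":
        return level == 1.0
    return _wrap_angle(level) == 0.0


def evaluate_consistency(
    model: DetectionModel,
    explainer: Explainer,
    dataset: Sequence[AnnotatedImage],
    perturbations: Sequence[PerturbationSpec] | PerturbationSpec | None = None,
    threshold: float = 0.5,
    seed: int = 0,
) -> CriterionResult:
    """Compare each image's explanation against its perturbed counterparts.

    Returns per-image SSIM/MSE/IoU at every perturbation level plus model
    correctness, with bootstrap-CI summaries keyed by ``kind:level``.
    Identity levels (dose factor 1, angle 0) compare a heatmap with itself
    and must be exact.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    if perturbations is None:
        perturbations = default_perturbations(seed=seed)
    elif isinstance(perturbations, PerturbationSpec):
        perturbations = [perturbations]

    records: list[dict] = []
    n_degenerate = 0
    for idx, img in enumerate(dataset):
        reference = explainer(model, img)
        if reference.degenerate:
            n_degenerate += 1
        for spec in perturbations:
            for level in spec.levels:
                if _is_identity(spec.kind, level):
                    moved = img
                else:
                    level_seed = int(
                        np.random.SeedSequence(
                            entropy=spec.seed,
                            spawn_key=(idx, abs(int(level * 1000))),
                        ).generate_state(1)[0]
                        & 0x7FFFFFFF
                    )
                    moved = perturb(img, spec.kind, level, seed=level_seed)
                explained = explainer(model, moved)
                values, mask = explained.values, None
                if spec.kind == "rotation" and not _is_identity(spec.kind, level):
                    values, mask = inverse_rotate(values, level)
                bundle = compare_heatmaps(reference.values, values, mask=mask)
                score, _ = model.score(moved)
                records.append(
                    {
                        "image_id": idx,
                        "condition": f"{spec.kind}:{level:g}",
                        "ssim": bundle.ssim,
                        "mse": bundle.mse,
                        "iou": bundle.iou,
                        "model_correct": bool(
                            (score >= threshold) == img.lesion_present
                        ),
                    }
                )

    flags = []
    if n_degenerate > DEGENERATE_FLAG_FRACTION * len(dataset):
        flags.append(
            "unreliable: explainer degenerate on "
            f"{n_degenerate}/{len(dataset)} images"
        )
    return CriterionResult(
        criterion="consistency",
        per_image=records,
        summary=summarize_records(records, seed=seed),
        model_accuracy=accuracy_by_condition(records),
        flags=flags,
    )
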