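"""Heatmap explainers behind a single callable contract.

An explainer is a callable ``explainer(model, image) -> Heatmap``. Two CAM
(class activation map) methods are implemented on top of the
:class:`~camaudit.models.DetectionModel` contract:

* :class:`EigenCAM` — the first right singular vector of the layer's
  activation matrix (channels × pixels), without mean-centering. It captures
  the dominant spatial pattern of the features regardless of how the model
  weighs them.
* :class:`AblationCAM` — channels weighted by the relative score drop when
  each is zeroed, so the map reflects what the model's decision actually
  depends on.

Two reference explainers used for calibration and fidelity controls live
here too: :class:`GroundTruthExplainer` (the oracle: the indicator of the
true lesion box) and :class:`ConstantExplainer` (deliberately
model-independent; any fidelity check must flag it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Protocol

import numpy as np
from skimage.transform import resize

from .models import DetectionModel
from .synthetic import AnnotatedImage

_EPS = 1e-12


@dataclass(frozen=True)
class Heatmap:
    """A normalized 2-D explanation map tied to one input image.

    ``values`` lie in [0, 1] at input resolution with min 0 and max 1,
    except for a degenerate (constant) raw map which is all zeros and
    carries ``degenerate=True``.
    """

    values: np.ndarray
    source_layer: str
    method: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or not np.all(np.isfinite(v)):
            raise ValueError("heatmap values must be a finite 2-D array")
        if v.min() < -_EPS or v.max() > 1.0 + _EPS:
            raise ValueError("heatmap values must lie in [0, 1]")
        object.__setattr__(self, "values", v)


class Explainer(Protocol):
    """Contract every heatmap explainer satisfies."""

    name: str

    def __call__(self, model: DetectionModel, image: AnnotatedImage) -> Heatmap:
        ...


def _finalize(
    raw: np.ndarray, shape: tuple[int, int], layer: str, method: str
) -> Heatmap:
    """Clamp negatives, upsample bilinearly to input size, min-max normalize."""
    raw = np.maximum(np.asarray(raw, dtype=float), 0.0)
    if raw.shape != shape:
        raw = resize(raw, shape, order=1, mode="edge", anti_aliasing=False)
    lo, hi = float(raw.min()), float(raw.max())
    if hi - lo < _EPS:
        return Heatmap(np.zeros(shape), layer, method, degenerate=True)
    return Heatmap((raw - lo) / (hi - lo), layer, method)


class EigenCAM:
    """Principal-component heatmap of a layer's activations.

    The activation stack is reshaped to channels × pixels and the first
    right singular vector of the raw (uncentered) matrix is reshaped back to
    a spatial map. The SVD sign ambiguity is fixed by requiring a
    non-negative spatial mean, so outputs are reproducible across
    linear-algebra backends.
    """

    def __init__(self, layer: Optional[str] = None):
        self.layer = layer
        self.name = "eigen_cam"

    def __call__(self, model: DetectionModel, image: AnnotatedImage) -> Heatmap:
        layer = self.layer or model.cam_layer
        acts = np.asarray(model.activations(image, layer), dtype=float)
        if acts.ndim != 3 or acts.shape[0] < 1:
            raise ValueError("layer must expose a CxHxW activation stack")
        c, h, w = acts.shape
        if not acts.any():
            return Heatmap(np.zeros(image.shape), layer, self.name, degenerate=True)
        mat = acts.reshape(c, h * w)
        _, _, vt = np.linalg.svd(mat, full_matrices=False)
        v1 = vt[0]
        if v1.mean() < 0:
            v1 = -v1
        return _finalize(v1.reshape(h, w), image.shape, layer, self.name)


def eigen_cam(
    model: DetectionModel, image: AnnotatedImage, layer: Optional[str] = None
) -> Heatmap:
    """Functional form of :class:`EigenCAM`."""
    return EigenCAM(layer)(model, image)


class AblationCAM:
    """Channel-ablation heatmap.

    With baseline score ``y`` and per-channel ablated scores ``y_c``, each
    channel's weight is ``(y - y_c) / y`` (the relative score drop when the
    channel is removed); the heatmap is the positive part of the weighted
    channel sum. Weights are invariant to positive rescaling of the score.
    """

    def __init__(self, layer: Optional[str] = None):
        self.layer = layer
        self.name = "ablation_cam"

    def channel_weights(
        self, model: DetectionModel, image: AnnotatedImage, layer: str
    ) -> np.ndarray:
        y, _ = model.score(image)
        if abs(y) < _EPS:
            raise ZeroDivisionError("baseline score is zero")
        acts = model.activations(image, layer)
        n_ch = acts.shape[0]
        weights = np.empty(n_ch)
        for ch in range(n_ch):
            try:
                ablated = acts.copy()
                ablated[ch] = 0.0
                y_c = model.score_from_activations(image, layer, ablated)
            except NotImplementedError:
                y_c = model.with_ablated_channel(layer, ch).score(image)[0]
            weights[ch] = (y - y_c) / y
        return weights

    def __call__(self, model: DetectionModel, image: AnnotatedImage) -> Heatmap:
        layer = self.layer or model.cam_layer
        acts = np.asarray(model.activations(image, layer), dtype=float)
        try:
            weights = self.channel_weights(model, image, layer)
        except ZeroDivisionError:
            return Heatmap(np.zeros(image.shape), layer, self.name, degenerate=True)
        cam = np.tensordot(weights, acts, axes=1)
        return _finalize(cam, image.shape, layer, self.name)


def ablation_cam(
    model: DetectionModel, image: AnnotatedImage, layer: Optional[str] = None
) -> Heatmap:
    """Functional form of :class:`AblationCAM`."""
    return AblationCAM(layer)(model, image)


class GroundTruthExplainer:
    """Oracle explainer: the indicator map of the true lesion box.

    Lesion-absent images yield a degenerate all-zero map. Used to pin the
    upper bound of plausibility (its ROI reproduces the ground-truth box).
    """

    name = "ground_truth_oracle"

    def __call__(self, model: DetectionModel, image: AnnotatedImage) -> Heatmap:
        values = np.zeros(image.shape)
        if image.lesion_bbox is None:
            return Heatmap(values, "ground_truth", self.name, degenerate=True)
        r0, c0, r1, c1 = image.lesion_bbox
        values[r0:r1, c0:c1] = 1.0
        return Heatmap(values, "ground_truth", self.name)


class ConstantExplainer:
    """Model-independent explainer returning the same map for every input.

    A negative control for fidelity checks: its explanations cannot change
    under any model intervention, so every check must flag it.
    """

    name = "constant"

    def __init__(self, value: float = 0.5):
        self.value = float(value)

    def __call__(self, model: DetectionModel, image: AnnotatedImage) -> Heatmap:
        return Heatmap(
            np.full(image.shape, np.clip(self.value, 0.0, 1.0)),
            "none",
            self.name,
            degenerate=True,
        )
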