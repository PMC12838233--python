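"""Detection models evaluated by the framework.

The framework only assumes the :class:`DetectionModel` contract: a scalar
lesion-presence score with a predicted box, per-layer spatial activations,
and non-mutating weight perturbation (full layer re-initialization and
single-channel ablation). Two desk-scale reference models are shipped:

* :func:`template_detector` — a transparent matched filter (normalized
  cross-correlation with the generator's lesion profile). Its true evidence
  region is the correlation peak, which makes it the substrate for the
  white-box fidelity check.
* :func:`train_small_cnn` — a compact convolutional network (three random
  seeded convolution layers and a trained logistic readout over pooled
  channel statistics) standing in for a full detection network at desk
  scale. It exposes its last convolution layer for CAM explainers.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats
from skimage.feature import match_template

from .synthetic import AnnotatedImage, lesion_profile

Box = tuple[int, int, int, int]


@dataclass(frozen=True)
class EvalResult:
    """Dataset-level detection performance.

    ``auc`` is ``None`` (undefined) when the dataset contains one class only.
    """

    accuracy: float
    auc: Optional[float]
    threshold: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")
        if self.auc is not None and not 0.0 <= self.auc <= 1.0:
            raise ValueError("auc must lie in [0, 1]")


class DetectionModel(abc.ABC):
    """Contract every detector plugs into the framework through.

    Scores are deterministic given weights and input; the ``with_*``
    constructors return modified copies and never mutate the original.
    """

    #: ordered names of perturbable layers
    layer_names: tuple[str, ...]
    #: default layer CAM explainers read activations from
    cam_layer: str

    @abc.abstractmethod
    def score(self, image: AnnotatedImage) -> tuple[float, Optional[Box]]:
        """Lesion-presence score in [0, 1] and predicted box."""

    @abc.abstractmethod
    def activations(self, image: AnnotatedImage, layer: str) -> np.ndarray:
        """C×H×W stack of feature maps at the named layer."""

    @abc.abstractmethod
    def with_randomized_layers(
        self, layers: Sequence[str], seed: int
    ) -> "DetectionModel":
        """Copy with the named layers' weights re-drawn from the
        initializer's distribution."""

    @abc.abstractmethod
    def with_ablated_channel(self, layer: str, channel: int) -> "DetectionModel":
        """Copy with one channel of the named layer forced to zero."""

    def score_from_activations(
        self, image: AnnotatedImage, layer: str, acts: np.ndarray
    ) -> float:
        """Re-score with the named layer's activations replaced by ``acts``.

        Optional fast path used by ablation-based explainers; the default
        raises and callers fall back to ``with_ablated_channel``.
        """
        raise NotImplementedError


def _sigmoid(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


# --------------------------------------------------------------------------
# white-box matched filter


class TemplateDetector(DetectionModel):
    """Normalized cross-correlation of the image with the lesion profile.

    The presence score is a logistic function of the maximum correlation;
    the predicted box is a lesion-sized box centred at the correlation
    argmax. Layers: ``smooth`` (two Gaussian-smoothed copies of the input)
    and ``features`` (the smoothed copies plus the correlation map); the
    correlation map is the model's entire decision path, so ablating it
    collapses the score to the no-signal value.
    """

    #: logistic steepness on the max-correlation axis
    GAIN = 25.0
    #: logistic midpoint: max correlation giving score 0.5 (between the
    #: typical background peak correlation and the typical lesion correlation)
    MIDPOINT = 0.66
    _SMOOTH_SIGMAS = (1.0, 2.0)

    def __init__(
        self,
        lesion_radius: int,
        _template: Optional[np.ndarray] = None,
        _smooth_kernels: Optional[list] = None,
        _ablated: Optional[frozenset] = None,
    ):
        if lesion_radius < 1:
            raise ValueError("lesion_radius must be >= 1")
        self.lesion_radius = int(lesion_radius)
        self.template = (
            lesion_profile(self.lesion_radius) if _template is None else _template
        )
        # None => exact Gaussian smoothing; arrays => randomized kernels
        self._smooth_kernels = _smooth_kernels or [None, None]
        self._ablated = _ablated or frozenset()
        self.layer_names = ("smooth", "features")
        self.cam_layer = "features"

    def _copy(self, **overrides) -> "TemplateDetector":
        kw = dict(
            lesion_radius=self.lesion_radius,
            _template=self.template,
            _smooth_kernels=list(self._smooth_kernels),
            _ablated=self._ablated,
        )
        kw.update(overrides)
        return TemplateDetector(**kw)

    def _check_size(self, image: AnnotatedImage) -> None:
        th, tw = self.template.shape
        h, w = image.shape
        if h < th or w < tw:
            raise ValueError("image smaller than the lesion template")

    def _smooth_maps(self, px: np.ndarray) -> list[np.ndarray]:
        maps = []
        for i, sigma in enumerate(self._SMOOTH_SIGMAS):
            kern = self._smooth_kernels[i]
            if kern is None:
                maps.append(ndimage.gaussian_filter(px, sigma=sigma, mode="reflect"))
            else:
                maps.append(ndimage.correlate(px, kern, mode="reflect"))
        return maps

    def _correlation_map(self, px: np.ndarray) -> np.ndarray:
        return match_template(px, self.template, pad_input=True)

    def _features(self, image: AnnotatedImage) -> np.ndarray:
        self._check_size(image)
        px = image.pixels
        stack = np.stack(self._smooth_maps(px) + [self._correlation_map(px)])
        for layer, ch in self._ablated:
            if layer == "features":
                stack[ch] = 0.0
            elif layer == "smooth" and ch < len(self._SMOOTH_SIGMAS):
                stack[ch] = 0.0
        return stack

    def _score_from_corr(self, corr: np.ndarray, shape) -> tuple[float, Box]:
        from .metrics import centered_box_start

        flat = int(np.argmax(corr))
        pr, pc = divmod(flat, corr.shape[1])
        m = float(corr[pr, pc])
        side = 2 * self.lesion_radius
        h, w = shape
        r0 = centered_box_start(pr, side, h)
        c0 = centered_box_start(pc, side, w)
        box = (r0, c0, r0 + side, c0 + side)
        return _sigmoid(self.GAIN * (m - self.MIDPOINT)), box

    def score(self, image: AnnotatedImage) -> tuple[float, Box]:
        feats = self._features(image)
        return self._score_from_corr(feats[-1], image.shape)

    def score_from_activations(
        self, image: AnnotatedImage, layer: str, acts: np.ndarray
    ) -> float:
        if layer != "features":
            raise NotImplementedError
        return self._score_from_corr(np.asarray(acts)[-1], image.shape)[0]

    def activations(self, image: AnnotatedImage, layer: str) -> np.ndarray:
        if layer == "features":
            return self._features(image)
        if layer == "smooth":
            px = image.pixels
            stack = np.stack(self._smooth_maps(px))
            for lay, ch in self._ablated:
                if lay == "smooth":
                    stack[ch] = 0.0
            return stack
        raise ValueError(f"unknown layer: {layer!r}")

    def with_randomized_layers(
        self, layers: Sequence[str], seed: int
    ) -> "TemplateDetector":
        unknown = set(layers) - set(self.layer_names)
        if unknown:
            raise ValueError(f"unknown layers: {sorted(unknown)}")
        out = self._copy()
        rng = np.random.default_rng(seed)
        if "smooth" in layers:
            kernels = []
            for _ in self._SMOOTH_SIGMAS:
                k = rng.standard_normal((7, 7))
                kernels.append(k / np.abs(k).sum())
            out = out._copy(_smooth_kernels=kernels)
        if "features" in layers:
            # re-initialized matched filter: smoothed zero-mean random kernel
            t = rng.standard_normal(self.template.shape)
            t = ndimage.gaussian_filter(t, sigma=1.0)
            t -= t.mean()
            t /= np.abs(t).max()
            out = out._copy(_template=t)
        return out

    def with_ablated_channel(self, layer: str, channel: int) -> "TemplateDetector":
        n = {"smooth": 2, "features": 3}.get(layer)
        if n is None:
            raise ValueError(f"unknown layer: {layer!r}")
        if not 0 <= channel < n:
            raise ValueError(f"channel {channel} out of range for {layer!r}")
        return self._copy(_ablated=self._ablated | {(layer, channel)})


def template_detector(lesion_radius: int) -> TemplateDetector:
    """White-box matched-filter detector for the generator's lesion profile."""
    return TemplateDetector(lesion_radius)


# --------------------------------------------------------------------------
# small convolutional network


def _conv2d(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Stride-1 'same' cross-correlation, x: (C,H,W), weights: (F,C,k,k).

    Large single-channel kernels (the first-layer filter bank) go through an
    FFT path; small mixing kernels use direct im2col, which is faster there.
    """
    from scipy.signal import fftconvolve

    n_ch, k = weights.shape[1], weights.shape[-1]
    if n_ch == 1 and k >= 9:
        flipped = weights[:, 0, ::-1, ::-1]
        return np.stack(
            [fftconvolve(x[0], f, mode="same") for f in flipped]
        )
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    return np.einsum("chwij,fcij->fhw", windows, weights, optimize=True)


def _pool2(x: np.ndarray) -> np.ndarray:
    """2x2 mean pooling on (C,H,W); trailing odd row/col dropped."""
    c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    return x[:, : h2 * 2, : w2 * 2].reshape(c, h2, 2, w2, 2).mean(axis=(2, 4))


_CNN_SHAPES = {
    "conv1": (8, 1, 15, 15),
    "conv2": (12, 8, 5, 5),
    "conv3": (12, 12, 3, 3),
}
#: low-pass (Gaussian) and band-pass (difference-of-Gaussian) scales of the
#: fixed first-layer filter bank, in pixels
_BANK_LOWPASS_SIGMAS = (1.0, 2.0, 3.0)
_BANK_BANDPASS_SIGMAS = (1.5, 2.0, 3.0, 3.5)
_DOG_RATIO = 1.6


def _init_conv(shape: tuple, rng: np.random.Generator) -> np.ndarray:
    fan_in = shape[1] * shape[2] * shape[3]
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


def _gauss_kernel(sigma: float, k: int) -> np.ndarray:
    ax = np.arange(k, dtype=float) - k // 2
    rr, cc = np.meshgrid(ax, ax, indexing="ij")
    g = np.exp(-(rr**2 + cc**2) / (2.0 * sigma**2))
    return g / g.sum()


def _filter_bank() -> np.ndarray:
    """Fixed first-layer bank: multi-scale Gaussians and centre-surround
    difference-of-Gaussian kernels (one extra wide band-pass)."""
    k = _CNN_SHAPES["conv1"][-1]
    kernels = [_gauss_kernel(s, k) for s in _BANK_LOWPASS_SIGMAS]
    for s in _BANK_BANDPASS_SIGMAS:
        dog = _gauss_kernel(s, k) - _gauss_kernel(_DOG_RATIO * s, k)
        kernels.append(dog / np.abs(dog).sum())
    kernels.append(_gauss_kernel(1.0, k) - _gauss_kernel(2.5, k))
    return np.stack(kernels)[:, None]


def _instance_norm(x: np.ndarray) -> np.ndarray:
    m = x.mean(axis=(1, 2), keepdims=True)
    s = x.std(axis=(1, 2), keepdims=True)
    return (x - m) / np.maximum(s, 1e-6)


class SmallCNN(DetectionModel):
    """Compact convolutional presence classifier.

    Architecture: a fixed multi-scale filter bank (``conv1``: Gaussian and
    centre-surround kernels, instance-normalized — a scattering-style front
    end), two trained convolution layers (``conv2``, ``conv3``), and a
    trained logistic readout on per-channel mean and max of ``conv3``, which
    is also the layer CAM explainers read. All computation is plain numpy,
    so scores are bit-for-bit deterministic given weights and input.
    """

    def __init__(
        self,
        weights: dict,
        head_w: np.ndarray,
        head_b: float,
        box_size: int,
        seed: int,
        ablated: Optional[frozenset] = None,
    ):
        self.weights = weights
        self.head_w = head_w
        self.head_b = head_b
        self.box_size = box_size
        self.seed = seed
        self._ablated = ablated or frozenset()
        self.layer_names = ("conv1", "conv2", "conv3", "head")
        self.cam_layer = "conv3"

    # ---- forward pass -----------------------------------------------------

    def _zero_ablated(self, layer: str, maps: np.ndarray) -> np.ndarray:
        for lay, ch in self._ablated:
            if lay == layer:
                maps = maps.copy()
                maps[ch] = 0.0
        return maps

    def _forward_convs(self, px: np.ndarray, upto: str = "conv3") -> np.ndarray:
        # instance norm only after conv1: it puts the fixed band-pass
        # channels on a common scale before the trained mixing layers
        x = np.maximum(_instance_norm(_conv2d(px[None], self.weights["conv1"])), 0.0)
        x = self._zero_ablated("conv1", x)
        if upto == "conv1":
            return x
        x = np.maximum(_conv2d(_pool2(x), self.weights["conv2"]), 0.0)
        x = self._zero_ablated("conv2", x)
        if upto == "conv2":
            return x
        x = np.maximum(_conv2d(_pool2(x), self.weights["conv3"]), 0.0)
        x = self._zero_ablated("conv3", x)
        if upto == "conv3":
            return x
        raise ValueError(f"unknown layer: {upto!r}")

    def _pooled_features(self, conv3: np.ndarray) -> np.ndarray:
        return np.concatenate([conv3.mean(axis=(1, 2)), conv3.max(axis=(1, 2))])

    def _head_score(self, conv3: np.ndarray) -> float:
        f = self._pooled_features(conv3)
        return _sigmoid(float(self.head_w @ f + self.head_b))

    def score(self, image: AnnotatedImage) -> tuple[float, Box]:
        conv3 = self._forward_convs(image.pixels)
        s = self._head_score(conv3)
        # localization: channels weighted by their head max-feature weight
        n_ch = conv3.shape[0]
        w_max = np.maximum(self.head_w[n_ch:], 0.0)
        cam = np.tensordot(w_max, conv3, axes=1)
        from .metrics import centered_box_start

        scale = image.shape[0] / cam.shape[0]
        pr, pc = np.unravel_index(int(np.argmax(cam)), cam.shape)
        r, c = pr * scale, pc * scale
        h, w = image.shape
        r0 = centered_box_start(r, self.box_size, h)
        c0 = centered_box_start(c, self.box_size, w)
        return s, (r0, c0, r0 + self.box_size, c0 + self.box_size)

    def score_from_activations(
        self, image: AnnotatedImage, layer: str, acts: np.ndarray
    ) -> float:
        if layer != "conv3":
            raise NotImplementedError
        return self._head_score(np.asarray(acts, dtype=float))

    def activations(self, image: AnnotatedImage, layer: str) -> np.ndarray:
        if layer not in _CNN_SHAPES:
            raise ValueError(f"layer {layer!r} has no spatial activations")
        return self._forward_convs(image.pixels, upto=layer)

    # ---- perturbation constructors ---------------------------------------

    def _copy(self, **overrides) -> "SmallCNN":
        kw = dict(
            weights=dict(self.weights),
            head_w=self.head_w,
            head_b=self.head_b,
            box_size=self.box_size,
            seed=self.seed,
            ablated=self._ablated,
        )
        kw.update(overrides)
        return SmallCNN(**kw)

    def with_randomized_layers(self, layers: Sequence[str], seed: int) -> "SmallCNN":
        unknown = set(layers) - set(self.layer_names)
        if unknown:
            raise ValueError(f"unknown layers: {sorted(unknown)}")
        rng = np.random.default_rng(seed)
        weights = dict(self.weights)
        head_w, head_b = self.head_w, self.head_b
        for layer in self.layer_names:  # fixed order => reproducible draws
            if layer not in layers:
                continue
            if layer == "head":
                head_w = rng.standard_normal(self.head_w.shape)
                head_b = float(rng.standard_normal())
            else:
                weights[layer] = _init_conv(_CNN_SHAPES[layer], rng)
        return self._copy(weights=weights, head_w=head_w, head_b=head_b)

    def with_ablated_channel(self, layer: str, channel: int) -> "SmallCNN":
        if layer not in _CNN_SHAPES:
            raise ValueError(f"cannot ablate layer {layer!r}")
        if not 0 <= channel < _CNN_SHAPES[layer][0]:
            raise ValueError(f"channel {channel} out of range for {layer!r}")
        return self._copy(ablated=self._ablated | {(layer, channel)})


def _conv_windows(x: np.ndarray, k: int) -> np.ndarray:
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p)))
    return np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))


def _conv2d_transpose(dy: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Gradient of the 'same' convolution w.r.t. its input."""
    flipped = weights[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
    return _conv2d(dy, flipped)


def _unpool2(dp: np.ndarray, shape: tuple) -> np.ndarray:
    out = np.zeros(shape)
    h2, w2 = dp.shape[1], dp.shape[2]
    out[:, : h2 * 2, : w2 * 2] = (
        np.repeat(np.repeat(dp, 2, axis=1), 2, axis=2) / 4.0
    )
    return out


def train_small_cnn(
    dataset: Sequence[AnnotatedImage],
    epochs: int = 60,
    seed: int = 0,
    learning_rate: float = 3e-3,
) -> SmallCNN:
    """Train the small CNN on a labelled phantom dataset.

    The fixed filter-bank front end (conv1 + instance norm + pooling) is
    computed once per image and cached; ``conv2``, ``conv3`` and the
    logistic head are then fit by full-batch Adam on the cross-entropy
    loss for ``epochs`` passes. Training is deterministic given ``seed``.
    """
    labels = np.array([img.lesion_present for img in dataset], dtype=float)
    if len(labels) == 0 or labels.min() == labels.max():
        raise ValueError("dataset must contain both classes")
    rng = np.random.default_rng(seed)
    w2 = _init_conv(_CNN_SHAPES["conv2"], rng)
    w3 = _init_conv(_CNN_SHAPES["conv3"], rng)
    n_ch = _CNN_SHAPES["conv3"][0]
    head_w = np.zeros(2 * n_ch)
    head_b = 0.0
    bank = _filter_bank()

    fronts = [
        _pool2(np.maximum(_instance_norm(_conv2d(img.pixels[None], bank)), 0.0))
        for img in dataset
    ]

    params = [w2, w3, head_w, np.array([head_b])]
    m_est = [np.zeros_like(p) for p in params]
    v_est = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    n = len(labels)
    for step in range(1, max(int(epochs), 1) + 1):
        grads = [np.zeros_like(p) for p in params]
        for f1, y in zip(fronts, labels):
            z2 = _conv2d(f1, params[0])
            a2 = np.maximum(z2, 0.0)
            p2 = _pool2(a2)
            z3 = _conv2d(p2, params[1])
            a3 = np.maximum(z3, 0.0)
            feats = np.concatenate([a3.mean(axis=(1, 2)), a3.max(axis=(1, 2))])
            s = _sigmoid(float(params[2] @ feats + params[3][0]))
            ds = s - y
            # backward: head -> conv3 -> conv2
            area3 = a3.shape[1] * a3.shape[2]
            da3 = np.broadcast_to(
                (ds * params[2][:n_ch])[:, None, None] / area3, a3.shape
            ).copy()
            w_max = ds * params[2][n_ch:]
            for c in range(n_ch):
                idx = np.unravel_index(int(np.argmax(a3[c])), a3[c].shape)
                da3[c][idx] += w_max[c]
            dz3 = da3 * (z3 > 0)
            grads[1] += np.einsum(
                "chwij,fhw->fcij", _conv_windows(p2, 3), dz3, optimize=True
            )
            dz2 = _unpool2(_conv2d_transpose(dz3, params[1]), a2.shape) * (z2 > 0)
            grads[0] += np.einsum(
                "chwij,fhw->fcij", _conv_windows(f1, 5), dz2, optimize=True
            )
            grads[2] += ds * feats
            grads[3] += ds
        for i, (p, g) in enumerate(zip(params, grads)):
            g = g / n
            m_est[i] = beta1 * m_est[i] + (1 - beta1) * g
            v_est[i] = beta2 * v_est[i] + (1 - beta2) * g * g
            m_hat = m_est[i] / (1 - beta1**step)
            v_hat = v_est[i] / (1 - beta2**step)
            p -= learning_rate * m_hat / (np.sqrt(v_hat) + eps)

    weights = {"conv1": bank, "conv2": params[0], "conv3": params[1]}
    return SmallCNN(
        weights=weights,
        head_w=params[2],
        head_b=float(params[3][0]),
        box_size=2 * _median_box_size(dataset),
        seed=seed,
    )


def _median_box_size(dataset: Sequence[AnnotatedImage]) -> int:
    sizes = [
        img.lesion_bbox[2] - img.lesion_bbox[0]
        for img in dataset
        if img.lesion_bbox is not None
    ]
    return int(np.median(sizes)) // 2 if sizes else 8


# --------------------------------------------------------------------------
# evaluation


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the Mann–Whitney rank statistic (tie-aware)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate_model(
    model: DetectionModel,
    dataset: Sequence[AnnotatedImage],
    threshold: float = 0.5,
) -> EvalResult:
    """Presence accuracy at ``threshold`` and Mann–Whitney AUC.

    On a one-class dataset the AUC is undefined and reported as ``None``.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    scores = np.array([model.score(img)[0] for img in dataset])
    labels = np.array([img.lesion_present for img in dataset], dtype=bool)
    accuracy = float(np.mean((scores >= threshold) == labels))
    try:
        auc = mann_whitney_auc(scores, labels)
    except ValueError:
        auc = None
    return EvalResult(accuracy=accuracy, auc=auc, threshold=threshold)


def equal_error_threshold(
    scores: Sequence[float], labels: Sequence[bool]
) -> float:
    """Operating point where false-positive and false-negative rates cross."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    cand = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    best, best_gap = 0.5, np.inf
    for t in cand:
        fpr = np.mean(scores[~labels] >= t) if (~labels).any() else 0.0
        fnr = np.mean(scores[labels] < t) if labels.any() else 0.0
        gap = abs(fpr - fnr)
        if gap < best_gap:
            best, best_gap = float(t), gap
    return best
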