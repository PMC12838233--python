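"""Synthetic mammography-like phantoms with exact lesion ground truth.

The generator produces grayscale 2-D images that mimic the properties an
explainability benchmark needs from a synthetic mammography dataset: a
textured parenchyma-like background, an optional additive lesion at a known
location, and acquisition metadata (relative radiation dose, rotation angle).
It is not a physical X-ray simulator; the background is correlated Gaussian
noise whose correlation length shrinks as the density proxy grows, and the
lesion is a radially symmetric Gaussian-profile blob.

Conventions used throughout the package: images are row-major 2-D float
arrays with intensities in [0, 1]; pixel coordinates are 0-based (row, col);
bounding boxes are axis-aligned half-open tuples
``(row_min, col_min, row_max, col_max)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

Box = tuple[int, int, int, int]

#: mean background intensity of generated phantoms (also the rotation /
#: deletion fill level, so masks do not introduce high-contrast edges)
BACKGROUND_MEAN = 0.35
#: standard deviation of the fine parenchyma-like texture
BACKGROUND_STD = 0.06
#: standard deviation / smoothing scale of the slowly varying tissue
#: brightness field (creates bright non-lesion regions, as dense tissue does)
LARGE_FIELD_STD = 0.10
LARGE_FIELD_SIGMA = 24.0
#: peak amplitude of the additive lesion profile
LESION_AMPLITUDE = 0.32
#: photon gain: expected counts per unit intensity at relative dose 1
DOSE_GAIN = 1000.0
#: relative dose at or above which the photon-noise branch is skipped
NOISE_FREE_DOSE = 1e6


@dataclass(frozen=True)
class AnnotatedImage:
    """A phantom image together with its exact ground truth and metadata.

    Attributes
    ----------
    pixels : 2-D float array, intensities clipped to [0, 1].
    lesion_present : whether the image contains a lesion.
    lesion_bbox : half-open pixel box around the lesion, ``None`` when absent.
    dose : relative radiation dose (1.0 = reference acquisition).
    density : texture-roughness proxy in [0, 1] standing in for breast density.
    seed : RNG seed that produced this image.
    angle : rotation (degrees) applied to the image; 0 for unperturbed.
    """

    pixels: np.ndarray
    lesion_present: bool
    lesion_bbox: Optional[Box] = None
    dose: float = 1.0
    density: float = 0.5
    seed: int = 0
    angle: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels must be finite")
        object.__setattr__(self, "pixels", np.clip(px, 0.0, 1.0))
        if self.lesion_present != (self.lesion_bbox is not None):
            raise ValueError("lesion_present must match presence of lesion_bbox")
        if self.lesion_bbox is not None:
            r0, c0, r1, c1 = self.lesion_bbox
            h, w = px.shape
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise ValueError("lesion_bbox must lie within image bounds")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class DatasetSpec:
    """Parameters of a generated phantom dataset.

    ``round(n_images * lesion_fraction)`` images carry exactly one lesion
    (round-half-even, matching Python's ``round``).
    """

    n_images: int = 150
    lesion_fraction: float = 0.5
    lesion_radius: int = 8
    dose: float = 1.0
    density: float = 0.5
    image_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if not 0.0 <= self.lesion_fraction <= 1.0:
            raise ValueError("lesion_fraction must lie in [0, 1]")
        if self.lesion_radius < 1:
            raise ValueError("lesion_radius must be >= 1")
        if self.lesion_radius >= self.image_size / 2:
            raise ValueError("lesion_radius must be smaller than image_size / 2")
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must lie in [0, 1]")


def _image_seed(dataset_seed: int, index: int) -> int:
    """Derive a per-image seed from the dataset seed by a splittable counter."""
    ss = np.random.SeedSequence(entropy=dataset_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _background(rng: np.random.Generator, size: int, density: float) -> np.ndarray:
    """Two-scale correlated Gaussian background.

    A slowly varying brightness field emulates tissue-density variation
    (bright regions that are not lesions), and a fine texture whose
    correlation length decreases with the density proxy emulates parenchymal
    roughness.
    """

    def _field(sigma: float) -> np.ndarray:
        f = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma,
                                    mode="reflect")
        sd = f.std()
        return f / sd if sd > 0 else f

    large = _field(LARGE_FIELD_SIGMA)
    corr_len = 0.4 + 1.2 * (1.0 - density)
    texture = _field(corr_len)
    return BACKGROUND_MEAN + LARGE_FIELD_STD * large + BACKGROUND_STD * texture


def lesion_profile(radius: int) -> np.ndarray:
    """Radially symmetric Gaussian lesion profile (peak 1) on a
    ``(2*radius+1)`` square support; sigma = radius / 2."""
    sigma = radius / 2.0
    ax = np.arange(-radius, radius + 1, dtype=float)
    rr, cc = np.meshgrid(ax, ax, indexing="ij")
    return np.exp(-(rr**2 + cc**2) / (2.0 * sigma**2))


def _render_image(
    seed: int,
    size: int,
    density: float,
    radius: int,
    with_lesion: bool,
    dose: float,
) -> AnnotatedImage:
    rng = np.random.default_rng(seed)
    px = _background(rng, size, density)
    bbox: Optional[Box] = None
    if with_lesion:
        # uniform in-bounds centre with a one-radius margin
        r = int(rng.integers(radius, size - radius))
        c = int(rng.integers(radius, size - radius))
        prof = lesion_profile(radius)
        px[r - radius : r + radius + 1, c - radius : c + radius + 1] += (
            LESION_AMPLITUDE * prof
        )
        bbox = (r - radius, c - radius, r + radius + 1, c + radius + 1)
    img = AnnotatedImage(
        pixels=px,
        lesion_present=with_lesion,
        lesion_bbox=bbox,
        dose=dose,
        density=density,
        seed=seed,
    )
    if dose < NOISE_FREE_DOSE:
        img = apply_dose(img, dose, seed=seed ^ 0x5EED)
    return img


def generate_dataset(spec: DatasetSpec) -> list[AnnotatedImage]:
    """Generate a phantom dataset with an exact lesion-present count.

    Deterministic for a fixed ``spec.seed``; exactly
    ``round(n_images * lesion_fraction)`` images contain one lesion, at
    positions uniformly random within bounds. Which slots carry a lesion is
    a seeded permutation, so presence is not correlated with index order.
    """
    n_lesion = round(spec.n_images * spec.lesion_fraction)
    flags = np.zeros(spec.n_images, dtype=bool)
    flags[:n_lesion] = True
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(0xABCD,)))
    flags = flags[rng.permutation(spec.n_images)]
    return [
        _render_image(
            seed=_image_seed(spec.seed, i),
            size=spec.image_size,
            density=spec.density,
            radius=spec.lesion_radius,
            with_lesion=bool(flags[i]),
            dose=spec.dose,
        )
        for i in range(spec.n_images)
    ]


def apply_dose(
    img: AnnotatedImage, relative_dose: float, seed: int = 0
) -> AnnotatedImage:
    """Re-acquire an image at a different relative radiation dose.

    Pixels are treated as mean photon counts scaled by a fixed gain
    ``DOSE_GAIN``; count noise is resampled as Poisson at rate
    ``dose * DOSE_GAIN * pixel`` and rescaled, so the expectation is
    preserved and the noise variance scales as ``1 / dose``. Ground truth
    and geometry are untouched. Doses at or above ``NOISE_FREE_DOSE``
    take a noise-free branch and return the input unchanged.
    """
    if relative_dose <= 0:
        raise ValueError("relative_dose must be positive")
    dose = relative_dose
    if dose >= NOISE_FREE_DOSE or math.isinf(dose):
        return replace(img, dose=dose)
    rate = dose * DOSE_GAIN
    rng = np.random.default_rng(seed)
    counts = rng.poisson(img.pixels * rate)
    return replace(img, pixels=counts / rate, dose=dose)


def _normalize_angle(angle: float) -> float:
    a = math.fmod(angle, 360.0)
    if a > 180.0:
        a -= 360.0
    elif a <= -180.0:
        a += 360.0
    return a


def _rotate_array(values: np.ndarray, angle: float, fill: float) -> np.ndarray:
    """Rotate about the image centre; right angles use an exact permutation."""
    a = _normalize_angle(angle)
    if a == 0.0:
        return values.copy()
    if a % 90.0 == 0.0 and values.shape[0] == values.shape[1]:
        return np.rot90(values, k=int(a // 90) % 4).copy()
    return ndimage.rotate(
        values, a, reshape=False, order=1, mode="constant", cval=fill
    )


def _rotate_box(box: Box, angle: float, shape: tuple[int, int]) -> Box:
    """Rotate box corners about the image centre and re-box (axis-aligned)."""
    a = math.radians(_normalize_angle(angle))
    h, w = shape
    # scipy's rotate convention: output(o) = input(R @ (o - c) + c); the
    # forward image of an input point p is therefore o = R^T (p - c) + c.
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    r0, c0, r1, c1 = box
    corners = np.array(
        [[r0, c0], [r0, c1 - 1], [r1 - 1, c0], [r1 - 1, c1 - 1]], dtype=float
    )
    rot = np.array([[math.cos(a), math.sin(a)], [-math.sin(a), math.cos(a)]])
    moved = (corners - [cr, cc]) @ rot + [cr, cc]
    rmin = int(np.clip(np.floor(moved[:, 0].min()), 0, h - 1))
    cmin = int(np.clip(np.floor(moved[:, 1].min()), 0, w - 1))
    rmax = int(np.clip(np.ceil(moved[:, 0].max()) + 1, rmin + 1, h))
    cmax = int(np.clip(np.ceil(moved[:, 1].max()) + 1, cmin + 1, w))
    return (rmin, cmin, rmax, cmax)


def rotate_image(img: AnnotatedImage, angle: float) -> AnnotatedImage:
    """Rotate an image about its centre (bilinear; out-of-frame pixels take
    the background mean). The lesion box is rotated and re-boxed; the
    ``angle`` metadata records the applied rotation."""
    a = _normalize_angle(angle)
    if abs(a) > 180.0:
        raise ValueError("angle must satisfy |angle| <= 180 after normalization")
    px = _rotate_array(img.pixels, a, fill=BACKGROUND_MEAN)
    bbox = None
    if img.lesion_bbox is not None:
        bbox = _rotate_box(img.lesion_bbox, a, img.pixels.shape)
    return replace(img, pixels=px, lesion_bbox=bbox, angle=img.angle + a)


def inverse_rotate(
    values: np.ndarray, angle: float
) -> tuple[np.ndarray, np.ndarray]:
    """Map a heatmap computed on a rotated image back to the original frame.

    Returns the realigned map together with a boolean validity mask marking
    pixels whose values survived the rotate/unrotate round trip (pixels that
    left the frame and were filled are excluded).
    """
    a = _normalize_angle(angle)
    back = _rotate_array(np.asarray(values, dtype=float), -a, fill=0.0)
    ones = np.ones_like(back)
    fwd_support = _rotate_array(ones, a, fill=0.0)
    support = _rotate_array(fwd_support, -a, fill=0.0)
    valid = support > 1.0 - 1e-6
    return back, valid


def perturb(
    img: AnnotatedImage, kind: str, level: float, seed: int = 0
) -> AnnotatedImage:
    """Apply one named input perturbation at the given level.

    ``kind='dose'``: ``level`` is the relative dose factor; a factor of
    exactly 1.0 denotes the original acquisition and returns the image
    unchanged (re-simulating noise is only meaningful for a changed dose).
    ``kind='rotation'``: ``level`` is the rotation angle in degrees.
    """
    if kind == "dose":
        if level == 1.0:
            return img
        return apply_dose(img, level, seed=seed)
    if kind == "rotation":
        return rotate_image(img, level)
    raise ValueError(f"unknown perturbation kind: {kind!r}")
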