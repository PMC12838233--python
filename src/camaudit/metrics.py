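"""Pairwise heatmap metrics and ROI extraction.

All criteria in the framework reduce to three per-image quantities: SSIM and
MSE between two heatmaps, and IoU either between two binarized heatmaps or
between two pixel boxes. Boxes follow the package-wide half-open
``(row_min, col_min, row_max, col_max)`` convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.metrics import structural_similarity

Box = tuple[int, int, int, int]

_CONST_EPS = 1e-12
#: default quantile defining each heatmap's "top" set for heatmap-vs-heatmap IoU
DEFAULT_TOP_QUANTILE = 0.1


@dataclass(frozen=True)
class MetricBundle:
    """SSIM / MSE / IoU between two heatmaps (or heatmap-derived sets)."""

    ssim: float
    mse: float
    iou: float

    def __post_init__(self) -> None:
        for name in ("ssim", "mse", "iou"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not -1.0 <= self.ssim <= 1.0 + 1e-9:
            raise ValueError("ssim must lie in [-1, 1]")
        if self.mse < 0:
            raise ValueError("mse must be non-negative")
        if not 0.0 <= self.iou <= 1.0:
            raise ValueError("iou must lie in [0, 1]")


@dataclass(frozen=True)
class ROIBox:
    """A fixed-size region of interest centred on a heatmap's peak."""

    box: Box
    peak: tuple[int, int]

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.box
        pr, pc = self.peak
        if not (r0 <= pr < r1 and c0 <= pc < c1):
            raise ValueError("peak must lie inside box")


def _top_set(values: np.ndarray, mask: np.ndarray, q: float) -> np.ndarray:
    """Boolean set of pixels at or above the map's own top-q quantile."""
    thr = np.quantile(values[mask], 1.0 - q)
    return (values >= thr) & mask


def compare_heatmaps(
    h1,
    h2,
    mask: Optional[np.ndarray] = None,
    top_quantile: float = DEFAULT_TOP_QUANTILE,
) -> MetricBundle:
    """SSIM (window 7, data range 1), MSE, and top-quantile IoU of two maps.

    A validity mask restricts all three metrics to the surviving pixels
    (SSIM is computed as the mean of the full SSIM map over the mask). Two
    constant maps are defined to have SSIM 1 when equal, 0 otherwise; the
    IoU binarizes each map at its own top-``top_quantile`` quantile, so it is
    invariant to monotone rescaling of either map.
    """
    a = np.asarray(getattr(h1, "values", h1), dtype=float)
    b = np.asarray(getattr(h2, "values", h2), dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"heatmap shapes differ: {a.shape} vs {b.shape}")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValueError("mask shape must match heatmap shape")
        if not mask.any():
            raise ValueError("mask must be non-empty")

    a_const = np.ptp(a[mask]) < _CONST_EPS
    b_const = np.ptp(b[mask]) < _CONST_EPS
    if a_const and b_const:
        ssim = 1.0 if abs(float(a[mask][0]) - float(b[mask][0])) < _CONST_EPS else 0.0
    else:
        _, ssim_map = structural_similarity(
            a, b, win_size=7, data_range=1.0, full=True
        )
        ssim = float(ssim_map[mask].mean())

    mse = float(np.mean((a[mask] - b[mask]) ** 2))
    ta = _top_set(a, mask, top_quantile)
    tb = _top_set(b, mask, top_quantile)
    union = np.count_nonzero(ta | tb)
    iou = float(np.count_nonzero(ta & tb) / union) if union else 1.0
    return MetricBundle(ssim=min(ssim, 1.0), mse=mse, iou=iou)


def centered_box_start(center: float, size: int, limit: int) -> int:
    """Start index of a length-``size`` interval centred (half-up rounding)
    on ``center``, shifted minimally to stay within ``[0, limit)``.

    Shared by ROI extraction and the detectors' predicted boxes so that a
    box derived from the same centre is identical everywhere.
    """
    start = int(np.floor(center - (size - 1) / 2.0 + 0.5))
    return int(np.clip(start, 0, limit - size))


def roi_from_heatmap(h, roi_size: tuple[int, int]) -> ROIBox:
    """Box of ``roi_size`` centred on the heatmap's highest-activation area.

    With a unique global maximum the box is centred on it. When the maximum
    is a plateau (several pixels tie), the box is centred on the plateau's
    centroid — so the ROI of a box-indicator map reproduces that box
    exactly, and a uniform map yields the centred ROI. The box is shifted
    minimally to stay in bounds and always contains the reported peak (the
    maximal pixel nearest the plateau centroid).
    """
    values = np.asarray(getattr(h, "values", h), dtype=float)
    height, width = roi_size
    n_rows, n_cols = values.shape
    if height < 1 or width < 1 or height > n_rows or width > n_cols:
        raise ValueError("roi_size must be positive and fit in the image")
    ties = np.argwhere(values == values.max())
    cr, cc = ties.mean(axis=0)
    r0 = centered_box_start(cr, height, n_rows)
    c0 = centered_box_start(cc, width, n_cols)
    nearest = ties[np.argmin(np.abs(ties - [cr, cc]).sum(axis=1))]
    peak = (
        int(np.clip(nearest[0], r0, r0 + height - 1)),
        int(np.clip(nearest[1], c0, c0 + width - 1)),
    )
    return ROIBox(box=(r0, c0, r0 + height, c0 + width), peak=peak)


def box_iou(a: Box, b: Box) -> float:
    """Intersection over union of two half-open pixel boxes."""
    for box in (a, b):
        r0, c0, r1, c1 = box
        if r1 <= r0 or c1 <= c0:
            raise ValueError(f"zero-area box: {box}")
    ir = max(0, min(a[2], b[2]) - max(a[0], b[0]))
    ic = max(0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ir * ic
    area = lambda x: (x[2] - x[0]) * (x[3] - x[1])  # noqa: E731
    return inter / (area(a) + area(b) - inter)
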