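"""Dataset, heatmap and model persistence.

Datasets are written as a directory of 16-bit PNGs plus one CSV manifest
(filename, ground truth, acquisition metadata); the same manifest schema
admits externally produced data into the framework. Heatmaps are written as
8-bit PNGs with a JSON sidecar recording provenance. Models are stored as a
single ``.npz`` archive (weights + architecture tag + seed).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .cams import Heatmap
from .models import DetectionModel, SmallCNN, TemplateDetector
from .synthetic import AnnotatedImage

_MANIFEST = "manifest.csv"
_PNG_MAX16 = 65535


def write_dataset(dataset: Sequence[AnnotatedImage], directory) -> Path:
    """Write images as 16-bit PNGs with a CSV manifest; returns the manifest
    path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for idx, img in enumerate(dataset):
        fname = f"image_{idx:05d}.png"
        arr = np.round(img.pixels * _PNG_MAX16).astype("<u2")
        Image.fromarray(arr).save(directory / fname)
        bbox = img.lesion_bbox or (None, None, None, None)
        rows.append(
            {
                "filename": fname,
                "lesion_present": img.lesion_present,
                "bbox_row_min": bbox[0],
                "bbox_col_min": bbox[1],
                "bbox_row_max": bbox[2],
                "bbox_col_max": bbox[3],
                "dose": img.dose,
                "density": img.density,
                "seed": img.seed,
                "angle": img.angle,
            }
        )
    manifest = directory / _MANIFEST
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset(directory) -> list[AnnotatedImage]:
    """Read a dataset written by :func:`write_dataset` (or any external data
    exported to the same manifest schema)."""
    directory = Path(directory)
    table = pd.read_csv(directory / _MANIFEST)
    out = []
    for row in table.itertuples(index=False):
        arr = np.asarray(Image.open(directory / row.filename), dtype=float)
        pixels = arr / _PNG_MAX16
        present = bool(row.lesion_present)
        bbox = None
        if present:
            bbox = (
                int(row.bbox_row_min),
                int(row.bbox_col_min),
                int(row.bbox_row_max),
                int(row.bbox_col_max),
            )
        out.append(
            AnnotatedImage(
                pixels=pixels,
                lesion_present=present,
                lesion_bbox=bbox,
                dose=float(row.dose),
                density=float(row.density),
                seed=int(row.seed),
                angle=float(row.angle),
            )
        )
    return out


def write_heatmap(heatmap: Heatmap, path, model: Optional[DetectionModel] = None) -> None:
    """8-bit PNG plus a JSON sidecar (method, layer, model hash, notes)."""
    path = Path(path)
    arr = np.round(heatmap.values * 255).astype(np.uint8)
    Image.fromarray(arr).save(path)
    sidecar = {
        "method": heatmap.method,
        "source_layer": heatmap.source_layer,
        "degenerate": heatmap.degenerate,
        "model_hash": _model_hash(model) if model is not None else None,
        "normalization": "per-image min-max; constant raw maps stored as zeros",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def _model_hash(model: DetectionModel) -> str:
    digest = hashlib.sha256()
    if isinstance(model, TemplateDetector):
        digest.update(model.template.tobytes())
    elif isinstance(model, SmallCNN):
        for name in sorted(model.weights):
            digest.update(model.weights[name].tobytes())
        digest.update(model.head_w.tobytes())
    return digest.hexdigest()[:16]


def save_model(model: DetectionModel, path) -> None:
    """Single-archive model persistence (weights + architecture tag + seed)."""
    path = Path(path).with_suffix(".npz")
    if isinstance(model, TemplateDetector):
        np.savez(
            path,
            arch="template",
            lesion_radius=model.lesion_radius,
            template=model.template,
        )
    elif isinstance(model, SmallCNN):
        np.savez(
            path,
            arch="small_cnn",
            head_w=model.head_w,
            head_b=model.head_b,
            box_size=model.box_size,
            seed=model.seed,
            **{f"weights_{k}": v for k, v in model.weights.items()},
        )
    else:
        raise TypeError(f"cannot save model of type {type(model).__name__}")


def load_model(path) -> DetectionModel:
    with np.load(Path(path).with_suffix(".npz"), allow_pickle=False) as data:
        arch = str(data["arch"])
        if arch == "template":
            return TemplateDetector(
                int(data["lesion_radius"]), _template=data["template"]
            )
        if arch == "small_cnn":
            weights = {
                k[len("weights_"):]: data[k]
                for k in data.files
                if k.startswith("weights_")
            }
            return SmallCNN(
                weights=weights,
                head_w=data["head_w"],
                head_b=float(data["head_b"]),
                box_size=int(data["box_size"]),
                seed=int(data["seed"]),
            )
    raise ValueError(f"unknown architecture tag: {arch!r}")


def write_criterion_csv(result, path) -> None:
    """Tidy per-image table of a criterion result as CSV."""
    result.to_frame().to_csv(Path(path), index=False)


def write_criterion_json(result, path) -> None:
    """Summary (means, CIs, accuracy, flags) of a criterion result as JSON."""
    payload = {
        "criterion": result.criterion,
        "summary": result.summary,
        "model_accuracy": result.model_accuracy,
        "flags": result.flags,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
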