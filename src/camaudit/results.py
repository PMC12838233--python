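"""Criterion result container shared by the three quantitative criteria."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bootstrap_mean_ci


@dataclass
class CriterionResult:
    """Per-image records plus recomputable aggregates for one criterion.

    ``per_image`` holds tidy records (one dict per image × condition with at
    least ``image_id`` and ``condition`` keys plus metric columns);
    ``summary`` maps condition → metric → ``{mean, ci_low, ci_high}``;
    ``model_accuracy`` maps condition → presence accuracy. ``flags`` carries
    qualitative verdict annotations (e.g. degenerate-explainer warnings).
    """

    criterion: str
    per_image: list[dict]
    summary: dict[str, dict[str, dict[str, float]]]
    model_accuracy: dict[str, float]
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-image table (one row per image × condition)."""
        return pd.DataFrame(self.per_image)

    def recompute_summary(self, seed: int = 0) -> dict:
        """Rebuild the summary from the per-image records (the stored
        summary must always equal this)."""
        return summarize_records(self.per_image, seed=seed)


_NON_METRIC_KEYS = {"image_id", "condition", "model_correct", "flagged"}


def summarize_records(records: list[dict], seed: int = 0) -> dict:
    """Mean and 95% bootstrap CI per metric per condition."""
    out: dict[str, dict[str, dict[str, float]]] = {}
    conditions = sorted({r["condition"] for r in records})
    for cond in conditions:
        rows = [r for r in records if r["condition"] == cond]
        metrics = [
            k
            for k in rows[0]
            if k not in _NON_METRIC_KEYS and isinstance(rows[0][k], (int, float))
        ]
        out[cond] = {}
        for m in metrics:
            values = np.array([r[m] for r in rows if r[m] is not None], dtype=float)
            if values.size == 0:
                continue
            mean, lo, hi = bootstrap_mean_ci(values, seed=seed)
            out[cond][m] = {"mean": mean, "ci_low": lo, "ci_high": hi}
    return out


def accuracy_by_condition(records: list[dict]) -> dict[str, float]:
    out: dict[str, float] = {}
    for cond in sorted({r["condition"] for r in records}):
        flags = [r["model_correct"] for r in records
                 if r["condition"] == cond and r.get("model_correct") is not None]
        if flags:
            out[cond] = float(np.mean(flags))
    return out
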