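"""The explainability scorecard: descriptive card + gated quantitative report.

The card has two parts. The descriptive part documents the explainability
method itself — overview, context of use, limitations and recommendations,
validation setting. The quantitative part reports the three computable
criteria in their mandatory order (consistency → plausibility → fidelity)
followed by a usefulness placeholder, since usefulness can only be
established in a human reader study.

Gating: a criterion whose configured threshold is not met marks every later
criterion ``gated`` — their metrics are still computed and reported, but no
pass/fail verdict is attached, and the gating is structural (the status is
derived inside :func:`run_framework`, not supplied by the caller). The
framework itself ships **no** default thresholds: acceptability must be
justified per task and modality, so an unset threshold yields
``not_evaluated`` (metrics without verdicts).
"""

from __future__ import annotations

import json
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .cams import Explainer
from .consistency import PerturbationSpec, evaluate_consistency
from .fidelity import randomization_check
from .models import DetectionModel, TemplateDetector
from .plausibility import evaluate_plausibility
from .synthetic import AnnotatedImage

GateStatus = Literal["passed", "failed", "gated", "not_evaluated"]

CRITERION_ORDER = ("consistency", "plausibility", "fidelity")


class MethodOverview(BaseModel):
    name: str
    description: str = ""
    abbreviation: str = ""
    type: str = "local, post-hoc"
    citation: str = ""
    software: str = ""

    @field_validator("name")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("overview.name must be non-empty")
        return v


class ContextOfUse(BaseModel):
    audience: str = ""
    task: str
    model: str = ""

    @field_validator("task")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("context_of_use.task must be non-empty")
        return v


class DescriptiveCard(BaseModel):
    """Descriptive half of the card (method documentation)."""

    overview: MethodOverview
    context_of_use: ContextOfUse
    limitations_and_recommendations: list[str] = Field(default_factory=list)
    validation_setting: str = ""


class UsefulnessPlaceholder(BaseModel):
    """Usefulness requires a reader study; the card carries its design only."""

    status: str = "requires human study"
    task: str = ""
    study_arms: list[str] = Field(
        default_factory=lambda: ["with explanation", "without explanation"]
    )
    endpoints: list[str] = Field(
        default_factory=lambda: ["task performance", "time to decision"]
    )


class CriterionReport(BaseModel):
    """One criterion's metrics plus its gate verdict."""

    criterion: str
    summary: dict
    model_accuracy: dict = Field(default_factory=dict)
    flags: list[str] = Field(default_factory=list)
    gate_status: GateStatus = "not_evaluated"
    gate_metric: Optional[str] = None
    gate_value: Optional[float] = None
    gate_threshold: Optional[float] = None


class Scorecard(BaseModel):
    """Full two-part card with gating state and provenance stamps."""

    descriptive: DescriptiveCard
    quantitative: list[CriterionReport]
    usefulness: UsefulnessPlaceholder = Field(default_factory=UsefulnessPlaceholder)
    gate_status: dict[str, GateStatus] = Field(default_factory=dict)
    seed: int = 0
    package_version: str = __version__

    @field_validator("quantitative")
    @classmethod
    def _ordered(cls, reports: list[CriterionReport]) -> list[CriterionReport]:
        names = [r.criterion for r in reports]
        expected = [c for c in CRITERION_ORDER if c in names]
        if names != expected:
            raise ValueError(
                f"criteria must appear in the order {CRITERION_ORDER}, got {names}"
            )
        return reports


class FrameworkConfig(BaseModel):
    """Evaluation configuration. Thresholds have no defaults by design."""

    thresholds: dict[str, Optional[float]] = Field(default_factory=dict)
    dose_levels: list[float] = [1.0, 0.66, 0.5, 0.33]
    rotation_angles: list[float] = [0.0, 10.0, 25.0, 50.0]
    roi_size: Optional[tuple[int, int]] = None
    randomized_layers: Optional[list[str]] = None  # None => all layers
    presence_threshold: float = 0.5
    seed: int = 0


#: gate metric of each criterion (what the configured threshold applies to)
GATE_METRICS = {
    "consistency": "mean SSIM over perturbation levels",
    "plausibility": "mean IoU vs ground-truth lesion box",
    "fidelity": "randomization sensitivity (1 - mean pre/post SSIM)",
}


def run_framework(
    model: DetectionModel,
    explainer: Explainer,
    dataset: Sequence[AnnotatedImage],
    config: Optional[FrameworkConfig] = None,
    descriptive: Optional[DescriptiveCard] = None,
) -> Scorecard:
    """Run consistency → plausibility → fidelity and assemble the card.

    All three criteria are always computed and reported; the configured
    thresholds only determine verdicts. After the first failed criterion,
    later criteria carry status ``gated``; criteria without a configured
    threshold carry ``not_evaluated``.
    """
    config = config or FrameworkConfig()
    descriptive = descriptive or _default_descriptive(explainer, model)
    perturbations = [
        PerturbationSpec("dose", tuple(config.dose_levels), seed=config.seed),
        PerturbationSpec("rotation", tuple(config.rotation_angles), seed=config.seed),
    ]

    consistency = evaluate_consistency(
        model, explainer, dataset, perturbations,
        threshold=config.presence_threshold, seed=config.seed,
    )
    cons_value = float(
        np.mean([m["ssim"]["mean"] for m in consistency.summary.values()])
    )

    plausibility = evaluate_plausibility(
        model, explainer, dataset, roi_size=config.roi_size,
        threshold=config.presence_threshold, seed=config.seed,
    )
    plaus_value = plausibility.summary["lesion_present"]["iou"]["mean"]

    layers = config.randomized_layers or list(model.layer_names)
    fid_records = randomization_check(
        model, explainer, dataset, layers,
        seed=config.seed, mode="joint", threshold=config.presence_threshold,
    )
    control, randomized = fid_records[0], fid_records[1]
    fid_value = 1.0 - randomized.summary["ssim"]["mean"]
    fidelity_summary = {
        "control": control.summary,
        "randomized": randomized.summary,
        "sensitivity": fid_value,
        "accuracy_pre": randomized.accuracy_pre,
        "accuracy_post": randomized.accuracy_post,
    }

    reports = [
        CriterionReport(
            criterion="consistency",
            summary=consistency.summary,
            model_accuracy=consistency.model_accuracy,
            flags=consistency.flags,
            gate_metric=GATE_METRICS["consistency"],
            gate_value=cons_value,
        ),
        CriterionReport(
            criterion="plausibility",
            summary=plausibility.summary,
            model_accuracy=plausibility.model_accuracy,
            flags=plausibility.flags,
            gate_metric=GATE_METRICS["plausibility"],
            gate_value=plaus_value,
        ),
        CriterionReport(
            criterion="fidelity",
            summary=fidelity_summary,
            model_accuracy={
                "pre": randomized.accuracy_pre, "post": randomized.accuracy_post
            },
            flags=randomized.flags,
            gate_metric=GATE_METRICS["fidelity"],
            gate_value=fid_value,
        ),
    ]

    upstream_failed = False
    gate_status: dict[str, GateStatus] = {}
    for report in reports:
        threshold = config.thresholds.get(report.criterion)
        if upstream_failed:
            status: GateStatus = "gated"
        elif threshold is None:
            status = "not_evaluated"
        elif report.gate_value is not None and report.gate_value >= threshold:
            status = "passed"
        else:
            status = "failed"
            upstream_failed = True
        report.gate_status = status
        report.gate_threshold = threshold
        gate_status[report.criterion] = status

    usefulness = UsefulnessPlaceholder(task=descriptive.context_of_use.task)
    return Scorecard(
        descriptive=descriptive,
        quantitative=reports,
        usefulness=usefulness,
        gate_status=gate_status,
        seed=config.seed,
    )


def _default_descriptive(
    explainer: Explainer, model: DetectionModel
) -> DescriptiveCard:
    name = getattr(explainer, "name", type(explainer).__name__)
    model_desc = (
        "matched-filter template detector"
        if isinstance(model, TemplateDetector)
        else type(model).__name__
    )
    return DescriptiveCard(
        overview=MethodOverview(
            name=name,
            type="local, post-hoc heatmap",
            software=f"camaudit {__version__}",
        ),
        context_of_use=ContextOfUse(
            task="lesion detection on synthetic mammography phantoms",
            model=model_desc,
        ),
        validation_setting=(
            "synthetic phantoms with exact lesion ground truth; no human "
            "reader study performed"
        ),
    )


# --------------------------------------------------------------------------
# rendering


_STATUS_STRINGS = {
    "passed": "passed",
    "failed": "failed",
    "gated": "gated (upstream criterion failed)",
    "not_evaluated": "not evaluated (no threshold configured)",
}


def render_scorecard(card: Scorecard, format: str = "markdown") -> str:
    """Serialize the card as schema-backed JSON or two-section markdown."""
    if format == "json":
        return card.model_dump_json(indent=2)
    if format == "markdown":
        return _render_markdown(card)
    raise ValueError(f"unknown format: {format!r}")


def load_scorecard(text: str) -> Scorecard:
    """Validate and load a JSON card produced by :func:`render_scorecard`."""
    return Scorecard.model_validate_json(text)


def scorecard_schema() -> dict:
    """JSON schema of the card (the copy shipped in package data matches)."""
    return Scorecard.model_json_schema()


def _render_markdown(card: Scorecard) -> str:
    d = card.descriptive
    lines = [
        "# Explainability scorecard",
        "",
        "## Descriptive information",
        "",
        "### Overview of the method",
        "",
        f"- **Name**: {d.overview.name}",
        f"- **Description**: {d.overview.description}",
        f"- **Abbreviation**: {d.overview.abbreviation}",
        f"- **Type**: {d.overview.type}",
        f"- **Citation**: {d.overview.citation}",
        f"- **Software**: {d.overview.software}",
        "",
        "### Context of use",
        "",
        f"- **Audience**: {d.context_of_use.audience}",
        f"- **Task**: {d.context_of_use.task}",
        f"- **Model**: {d.context_of_use.model}",
        "",
        "### Limitations and recommendations",
        "",
    ]
    lines += [f"- {item}" for item in d.limitations_and_recommendations] or ["- none recorded"]
    lines += [
        "",
        "### Validation setting",
        "",
        d.validation_setting or "not described",
        "",
        "## Quantitative evaluation",
        "",
    ]
    for report in card.quantitative:
        lines += [
            f"### {report.criterion.capitalize()}",
            "",
            f"- **Status**: {_STATUS_STRINGS[report.gate_status]}",
            f"- **Gate metric**: {report.gate_metric}",
            f"- **Gate value**: {_fmt(report.gate_value)}",
            f"- **Gate threshold**: {_fmt(report.gate_threshold)}",
        ]
        for flag in report.flags:
            lines.append(f"- **Flag**: {flag}")
        lines.append("")
        lines += _summary_table(report.summary)
        if report.model_accuracy:
            acc = ", ".join(
                f"{k}: {_fmt(v)}" for k, v in report.model_accuracy.items()
            )
            lines += [f"Model accuracy — {acc}", ""]
    lines += [
        "### Usefulness",
        "",
        f"- **Status**: {card.usefulness.status}",
        f"- **Task**: {card.usefulness.task}",
        f"- **Study arms**: {', '.join(card.usefulness.study_arms)}",
        f"- **Endpoints**: {', '.join(card.usefulness.endpoints)}",
        "",
        f"_Seed {card.seed}; camaudit {card.package_version}._",
    ]
    return "\n".join(lines)


def _fmt(v) -> str:
    if v is None:
        return "—"
    if isinstance(v, float):
        return format(v, ".6g")
    return str(v)


def _summary_table(summary: dict) -> list[str]:
    rows = []
    for cond, metrics in summary.items():
        if not isinstance(metrics, dict):
            rows.append((cond, "", _fmt(metrics), "", ""))
            continue
        for metric, agg in metrics.items():
            if isinstance(agg, dict):
                rows.append(
                    (cond, metric, _fmt(agg.get("mean")),
                     _fmt(agg.get("ci_low")), _fmt(agg.get("ci_high")))
                )
            else:
                rows.append((cond, metric, _fmt(agg), "", ""))
    if not rows:
        return []
    out = [
        "| condition | metric | mean | CI low | CI high |",
        "| --- | --- | --- | --- | --- |",
    ]
    out += [f"| {a} | {b} | {c} | {d} | {e} |" for a, b, c, d, e in rows]
    out.append("")
    return out
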