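"""Metrics report: a stable JSON artifact for every workflow run.

The schema shipped at ``omicsfs/schemas/metrics.schema.json`` is generated
from the pydantic models below (``python -m omicsfs.report`` regenerates
it); :func:`validate_report` checks any loaded JSON document against them.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field

from .workflow import EvaluationSummary, WorkflowResult

SCHEMA_PATH = Path(__file__).parent / "schemas" / "metrics.schema.json"


class StepRecord(BaseModel):
    name: str
    n_kept: int
    n_dropped: int
    cutoff: float | None = None


class MetricsReport(BaseModel):
    """Serialized outcome of ``run`` or ``evaluate``."""

    tool: str = "omicsfs"
    mode: str  # "run" | "evaluate"
    task: str
    seed: int
    steps: list[StepRecord]
    n_features_per_step: list[int]
    selected_features: list[str]
    per_split_metrics: list[dict[str, float]] = Field(default_factory=list)
    per_split_n_features: list[int] = Field(default_factory=list)
    mean: dict[str, float] = Field(default_factory=dict)
    sd: dict[str, float] = Field(default_factory=dict)
    median_n_features: float | None = None
    training_metrics: dict[str, float] = Field(default_factory=dict)
    config: dict = Field(default_factory=dict)


def _config_echo(result_config) -> dict:
    return {
        "task": result_config.task,
        "steps": [{"name": s.name, "cutoff": s.resolved_cutoff()}
                  for s in result_config.steps],
        "rfe": {
            "enabled": result_config.rfe.enabled,
            "model": result_config.rfe.model,
            "cv_folds": result_config.rfe.cv_folds,
            "subset_sizes": result_config.rfe.subset_sizes,
        },
        "seed": result_config.seed,
    }


def report_from_run(result: WorkflowResult) -> MetricsReport:
    return MetricsReport(
        mode="run",
        task=result.config.task,
        seed=result.config.seed,
        steps=[StepRecord(name=s.step_name, n_kept=s.n_kept,
                          n_dropped=s.n_dropped, cutoff=s.cutoff)
               for s in result.steps],
        n_features_per_step=list(result.n_features_per_step),
        selected_features=list(result.final_feature_ids),
        training_metrics=dict(result.model.training_metrics),
        config=_config_echo(result.config),
    )


def report_from_evaluation(summary: EvaluationSummary,
                           result: WorkflowResult | None,
                           config) -> MetricsReport:
    steps = [] if result is None else [
        StepRecord(name=s.step_name, n_kept=s.n_kept, n_dropped=s.n_dropped,
                   cutoff=s.cutoff) for s in result.steps]
    return MetricsReport(
        mode="evaluate",
        task=config.task,
        seed=summary.seed,
        steps=steps,
        n_features_per_step=(
            [] if result is None else list(result.n_features_per_step)),
        selected_features=(
            [] if result is None else list(result.final_feature_ids)),
        per_split_metrics=summary.per_split_metrics,
        per_split_n_features=summary.per_split_n_features,
        mean=summary.mean,
        sd=summary.sd,
        median_n_features=summary.median_n_features,
        config=_config_echo(config),
    )


def dump_report(report: MetricsReport, path) -> None:
    Path(path).write_text(
        json.dumps(report.model_dump(), indent=2, sort_keys=True) + "\n")


def load_report(path) -> MetricsReport:
    return validate_report(json.loads(Path(path).read_text()))


def validate_report(doc: dict) -> MetricsReport:
    return MetricsReport.model_validate(doc)


def write_schema(path=SCHEMA_PATH) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(MetricsReport.model_json_schema(),
                               indent=2, sort_keys=True) + "\n")


if __name__ == "__main__":
    write_schema()
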