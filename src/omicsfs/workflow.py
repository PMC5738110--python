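"""Workflow composition and resampled performance estimation.

``run_workflow`` chains the configured filters (univariate relevance,
CM redundancy elimination, PCA) on the running matrix, applies RFE last
if enabled, and fits the wrapped learner on the surviving features. The
fitted result predicts new samples by replaying the same transforms.

``evaluate_workflow`` estimates generalization performance with repeated
randomized class-balanced (stratified) train/test splits: the entire
workflow -- every filter and the RFE -- is refit inside each split on the
training part only, and scored on the held-out part.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .core import (
    CLASSIFICATION,
    FeatureMatrix,
    FilterStepResult,
    Outcome,
    WorkflowConfig,
    drop_incomplete_features,
    validate_pair,
)
from .errors import DimensionMismatchError, StepError, ValidationError
from .multivariate import PCAProjection, correlation_matrix_filter, pca_filter
from .rfe import FittedModel, ModelSpec, RFEProfile, fit_final_model, rfe
from .univariate import filter_by_correlation, filter_by_information_gain

logger = logging.getLogger("omicsfs")


def compute_metrics(predicted, observed, task: str) -> dict[str, float]:
    """Task metrics: accuracy, or RMSE and R^2 (squared Pearson correlation).

    R^2 here is the squared correlation of predicted vs observed, the
    convention of resampling-based training frameworks; set
    ``r2_convention="ss"`` on EvaluationSummary consumers if 1 - SSE/SST
    is wanted (see ``compute_metrics_ss``). Constant predictions make the
    correlation undefined; R^2 is reported as 0 with a warning flag.
    """
    predicted = np.asarray(predicted)
    observed = np.asarray(observed)
    if len(predicted) != len(observed):
        raise DimensionMismatchError(
            f"predicted length {len(predicted)} != observed {len(observed)}")
    if len(observed) < 2:
        raise ValidationError("need at least 2 observations")
    if task == CLASSIFICATION:
        acc = float(np.mean(predicted.astype(str) == observed.astype(str)))
        return {"accuracy": acc}
    predicted = predicted.astype(float)
    observed = observed.astype(float)
    rmse = float(np.sqrt(np.mean((predicted - observed) ** 2)))
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        warnings.warn("constant predictions: R^2 undefined, reported as 0")
        return {"rmse": rmse, "r2": 0.0, "r2_undefined": 1.0}
    r = np.corrcoef(predicted, observed)[0, 1]
    return {"rmse": rmse, "r2": float(r ** 2)}


def compute_metrics_ss(predicted, observed) -> dict[str, float]:
    """Regression metrics with the 1 - SSE/SST convention for R^2."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    sse = float(((predicted - observed) ** 2).sum())
    sst = float(((observed - observed.mean()) ** 2).sum())
    rmse = float(np.sqrt(sse / len(observed)))
    return {"rmse": rmse, "r2": 1.0 - sse / sst if sst > 0 else 0.0}


@dataclass
class WorkflowResult:
    """Everything one workflow run produced, in execution order."""

    steps: list[FilterStepResult]
    pca: PCAProjection | None
    rfe_profile: RFEProfile | None
    final_feature_ids: list[str]
    model: FittedModel
    step_seconds: dict[str, float]
    config: WorkflowConfig
    n_features_per_step: list[int] = field(default_factory=list)

    def predict(self, X: FeatureMatrix) -> np.ndarray:
        """Predict new samples by replaying the fitted transform chain."""
        if self.pca is not None:
            pre_pca_ids = self.pca.feature_ids
            Z = self.pca.transform(X.select_features(pre_pca_ids),
                                   n_components=self.pca.n_retained)
            return self.model.predict(Z)
        return self.model.predict(X)


def run_workflow(X: FeatureMatrix, y: Outcome,
                 config: WorkflowConfig) -> WorkflowResult:
    """Execute the configured filter chain, then RFE, then the final fit.

    Features with missing cells are removed up front (complete-case
    deletion). Feature counts are non-increasing across steps; an empty
    feature set mid-chain aborts with the offending step named.
    """
    validate_pair(X, y)
    config.validate()
    steps: list[FilterStepResult] = []
    times: dict[str, float] = {}
    counts = [X.n_features]
    pca_proj: PCAProjection | None = None
    cur = X

    def _run(step_name, fn):
        nonlocal cur
        t0 = time.perf_counter()
        try:
            out = fn(cur)
        except Exception as e:  # noqa: BLE001 - re-raise with step context
            raise StepError(step_name, e) from e
        times[step_name] = time.perf_counter() - t0
        return out

    if not cur.is_complete:
        cur, res = _run("drop_incomplete", drop_incomplete_features)
        steps.append(res)
        counts.append(cur.n_features)
        logger.info("drop_incomplete: %d features kept", cur.n_features)

    for step in config.steps:
        cutoff = step.resolved_cutoff()
        if step.name == "univariate_corr":
            cur, res = _run(step.name,
                            lambda m: filter_by_correlation(m, y, cutoff))
            steps.append(res)
        elif step.name == "univariate_gain":
            cur, res = _run(step.name,
                            lambda m: filter_by_information_gain(m, y, cutoff))
            steps.append(res)
        elif step.name == "matrix_corr":
            cur, res = _run(step.name,
                            lambda m: correlation_matrix_filter(m, cutoff))
            steps.append(res)
        elif step.name == "pca":
            cur, pca_proj = _run(step.name,
                                 lambda m: pca_filter(m, var_retained=cutoff))
        counts.append(cur.n_features)
        logger.info("%s: %d features kept", step.name, cur.n_features)

    model_spec = _model_spec(config)
    rfe_profile: RFEProfile | None = None
    if config.rfe.enabled:
        sizes = config.rfe.subset_sizes
        if sizes is not None:
            pruned = [s for s in sizes if s <= cur.n_features]
            if len(pruned) < len(sizes):
                logger.warning(
                    "subset sizes exceeding %d features pruned: %s",
                    cur.n_features,
                    [s for s in sizes if s > cur.n_features])
            sizes = pruned or None
        t0 = time.perf_counter()
        rfe_profile = rfe(cur, y, model=model_spec,
                          cv_folds=config.rfe.cv_folds,
                          subset_sizes=sizes, seed=config.seed)
        cur = cur.select_features(rfe_profile.selected_feature_ids)
        times["rfe"] = time.perf_counter() - t0
        counts.append(cur.n_features)
        logger.info("rfe: %d features selected", cur.n_features)

    t0 = time.perf_counter()
    fitted = fit_final_model(cur, y, model=model_spec, seed=config.seed)
    times["final_fit"] = time.perf_counter() - t0

    assert all(b <= a for a, b in zip(counts, counts[1:])), \
        "feature counts must be non-increasing along the chain"
    return WorkflowResult(
        steps=steps,
        pca=pca_proj,
        rfe_profile=rfe_profile,
        final_feature_ids=list(cur.feature_ids),
        model=fitted,
        step_seconds=times,
        config=config,
        n_features_per_step=counts,
    )


def _model_spec(config: WorkflowConfig) -> ModelSpec:
    return ModelSpec(kind=config.rfe.model, **(config.rfe.model_options or {}))


@dataclass
class EvaluationSummary:
    """Resampled test performance over randomized class-balanced splits."""

    n_splits: int
    per_split_metrics: list[dict[str, float]]
    per_split_n_features: list[int]
    mean: dict[str, float]
    sd: dict[str, float]
    median_n_features: float
    seed: int
    per_split_selected: list[list[str]] = field(default_factory=list)
    per_split_train_idx: list[np.ndarray] = field(default_factory=list)

    @property
    def primary_metric(self) -> str:
        return "accuracy" if "accuracy" in self.mean else "rmse"


def split_seed(master_seed: int, i: int) -> int:
    """Per-split seed from the master seed by a fixed counter scheme."""
    ss = np.random.SeedSequence([int(master_seed), int(i)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def evaluate_workflow(X: FeatureMatrix, y: Outcome, config: WorkflowConfig,
                      n_splits: int = 20, train_fraction: float = 2 / 3,
                      seed: int | None = None,
                      balance: str = "stratify") -> EvaluationSummary:
    """Repeated stratified train/test resampling of the whole workflow.

    For each of ``n_splits`` repetitions: draw a class-balanced split,
    run the full workflow on the training part only, and score the
    held-out part. ``balance="downsample"`` first downsamples classes to
    the minority size before splitting.
    """
    validate_pair(X, y)
    if n_splits < 2:
        raise ValidationError("n_splits must be >= 2")
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError("train_fraction must be in (0, 1)")
    master = config.seed if seed is None else seed
    metrics_per_split: list[dict[str, float]] = []
    counts: list[int] = []
    selected: list[list[str]] = []
    train_indices: list[np.ndarray] = []

    for i in range(n_splits):
        s = split_seed(master, i)
        idx = np.arange(X.n_samples)
        if y.task == CLASSIFICATION and balance == "downsample":
            idx = _downsample(y, s)
        strat = (y.values[idx].astype(str)
                 if y.task == CLASSIFICATION else None)
        tr, te = train_test_split(idx, train_size=train_fraction,
                                  random_state=s, stratify=strat,
                                  shuffle=True)
        for _retry in range(5):
            if y.task != CLASSIFICATION or \
                    len(set(y.values[tr].astype(str))) >= 2:
                break
            tr, te = train_test_split(idx, train_size=train_fraction,
                                      random_state=s + _retry + 1,
                                      shuffle=True)
        else:
            raise ValidationError(
                "could not build a training split with >= 2 classes")
        split_config = config.replace(seed=s)
        result = run_workflow(X.select_samples(tr), y.select_samples(tr),
                              split_config)
        pred = result.predict(X.select_samples(te))
        metrics_per_split.append(
            compute_metrics(pred, y.values[te], y.task))
        counts.append(len(result.final_feature_ids))
        selected.append(list(result.final_feature_ids))
        train_indices.append(np.asarray(tr))

    keys = sorted(metrics_per_split[0])
    mean = {k: float(np.mean([m.get(k, 0.0) for m in metrics_per_split]))
            for k in keys}
    sd = {k: float(np.std([m.get(k, 0.0) for m in metrics_per_split],
                          ddof=1)) for k in keys}
    return EvaluationSummary(
        n_splits=n_splits,
        per_split_metrics=metrics_per_split,
        per_split_n_features=counts,
        mean=mean,
        sd=sd,
        median_n_features=float(np.median(counts)),
        seed=master,
        per_split_selected=selected,
        per_split_train_idx=train_indices,
    )


def _downsample(y: Outcome, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    labels = y.values.astype(str)
    levels, counts = np.unique(labels, return_counts=True)
    m = counts.min()
    keep = []
    for lev in levels:
        pos = np.where(labels == lev)[0]
        keep.append(rng.choice(pos, size=m, replace=False))
    return np.sort(np.concatenate(keep))
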