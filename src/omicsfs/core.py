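"""Core domain types: feature matrices, outcomes, filter results, configs.

The canonical in-memory orientation is samples-as-rows. Missing values are
represented as NaN in the value matrix; every filtering stage requires a
complete matrix, obtained via :func:`drop_incomplete_features`
(feature-wise complete-case deletion -- no imputation).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ClassSizeError,
    ConfigError,
    ConstantOutcomeError,
    DimensionMismatchError,
    DuplicateIdError,
    NoCompleteFeaturesError,
    ValidationError,
)

CLASSIFICATION = "classification"
REGRESSION = "regression"

#: valid filter step names, in the vocabulary of the workflow:
#: ``univariate_corr`` (a.k.a. X2), ``univariate_gain`` (information gain),
#: ``matrix_corr`` (CM redundancy filter), ``pca`` (variance-retention filter).
FILTER_STEPS = ("univariate_corr", "univariate_gain", "matrix_corr", "pca")

DEFAULT_CUTOFFS = {
    "univariate_corr": 0.30,
    "univariate_gain": 0.0,
    "matrix_corr": 0.75,
    "pca": 0.95,
}


def _check_unique(ids, what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise DuplicateIdError(f"duplicate {what}: {sorted(set(dups))}")
    return ids


@dataclass
class FeatureMatrix:
    """A samples x features table of real values, NaN marking missing cells."""

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionMismatchError("values must be a 2-D array")
        n, p = self.values.shape
        if n < 2:
            raise ValidationError(f"need at least 2 samples, got {n}")
        if p < 1:
            raise ValidationError("need at least 1 feature")
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        self.feature_ids = _check_unique(self.feature_ids, "feature ids")
        if len(self.sample_ids) != n:
            raise DimensionMismatchError(
                f"{len(self.sample_ids)} sample ids != {n} rows"
            )
        if len(self.feature_ids) != p:
            raise DimensionMismatchError(
                f"{len(self.feature_ids)} feature ids != {p} columns"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def is_complete(self) -> bool:
        return bool(np.isfinite(self.values).all())

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)),
                   list(df.columns.astype(str)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.copy(), index=list(self.sample_ids),
                            columns=list(self.feature_ids))

    def select_features(self, ids: list[str]) -> "FeatureMatrix":
        """Subset to the given feature ids (in the given order)."""
        pos = {f: j for j, f in enumerate(self.feature_ids)}
        try:
            cols = [pos[i] for i in ids]
        except KeyError as e:
            raise DimensionMismatchError(f"unknown feature id {e}") from None
        return FeatureMatrix(self.values[:, cols], list(self.sample_ids),
                             list(ids))

    def select_samples(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(self.values[idx],
                             [self.sample_ids[i] for i in idx],
                             list(self.feature_ids))


@dataclass
class Outcome:
    """Per-sample target: class labels (strings) or continuous values."""

    task: str
    values: np.ndarray
    class_levels: list[str] | None = None

    def __post_init__(self):
        if self.task not in (CLASSIFICATION, REGRESSION):
            raise ValidationError(f"unknown task '{self.task}'")
        if self.task == CLASSIFICATION:
            self.values = np.asarray([str(v) for v in self.values], dtype=object)
            if self.class_levels is None:
                self.class_levels = sorted(set(self.values))
            else:
                self.class_levels = [str(c) for c in self.class_levels]
                unknown = set(self.values) - set(self.class_levels)
                if unknown:
                    raise ValidationError(
                        f"labels not in class_levels: {sorted(unknown)}")
        else:
            self.values = np.asarray(self.values, dtype=float)
            self.class_levels = None

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def numeric(self) -> np.ndarray:
        """Numeric view: 0/1 encoding in class_levels order for binary
        classification, raw values for regression."""
        if self.task == REGRESSION:
            return self.values
        if len(self.class_levels) != 2:
            raise ValidationError(
                "numeric encoding defined only for binary classification")
        return np.asarray(
            [self.class_levels.index(v) for v in self.values], dtype=float)

    def select_samples(self, idx) -> "Outcome":
        idx = np.asarray(idx)
        return Outcome(self.task, self.values[idx],
                       class_levels=list(self.class_levels)
                       if self.class_levels else None)


#: drop_reason vocabulary for FilterStepResult
DROP_REASONS = ("below_cutoff", "redundant_pair", "zero_variance",
                "missing_values")


@dataclass
class FilterStepResult:
    """Bookkeeping for one filter step: what survived, what fell, and why."""

    step_name: str
    kept_feature_ids: list[str]
    dropped_feature_ids: list[str]
    scores: dict[str, float]
    drop_reason: dict[str, str]
    cutoff: float | None = None

    def __post_init__(self):
        kept, dropped = set(self.kept_feature_ids), set(self.dropped_feature_ids)
        if kept & dropped:
            raise ValidationError("kept and dropped feature sets overlap")
        for f in self.dropped_feature_ids:
            reason = self.drop_reason.get(f)
            if reason not in DROP_REASONS:
                raise ValidationError(
                    f"dropped feature '{f}' has invalid drop reason {reason!r}")

    @property
    def n_kept(self) -> int:
        return len(self.kept_feature_ids)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_feature_ids)


@dataclass
class FilterStep:
    """One configured filter step; cutoff None means the step's default."""

    name: str
    cutoff: float | None = None

    def resolved_cutoff(self) -> float:
        return DEFAULT_CUTOFFS[self.name] if self.cutoff is None else self.cutoff


@dataclass
class RFEConfig:
    enabled: bool = True
    model: str = "random_forest"  # random_forest | svm_radial
    cv_folds: int = 10
    subset_sizes: list[int] | None = None
    #: extra ModelSpec keywords (e.g. {"n_trees": 100})
    model_options: dict = field(default_factory=dict)


@dataclass
class WorkflowConfig:
    """Ordered filter steps plus the optional RFE wrapper stage."""

    task: str
    steps: list[FilterStep] = field(default_factory=list)
    rfe: RFEConfig = field(default_factory=RFEConfig)
    seed: int = 0

    def __post_init__(self):
        self.steps = [FilterStep(**s) if isinstance(s, dict) else s
                      for s in self.steps]
        if isinstance(self.rfe, dict):
            self.rfe = RFEConfig(**self.rfe)
        self.validate()

    def validate(self) -> "WorkflowConfig":
        if self.task not in (CLASSIFICATION, REGRESSION):
            raise ConfigError(f"unknown task '{self.task}'")
        for s in self.steps:
            if s.name not in FILTER_STEPS:
                raise ConfigError(
                    f"unknown step '{s.name}'; valid steps: {FILTER_STEPS}")
        if self.task == REGRESSION and any(
                s.name == "univariate_gain" for s in self.steps):
            raise ConfigError(
                "univariate_gain is defined for classification only")
        names = [s.name for s in self.steps]
        if "pca" in names and "matrix_corr" in names[names.index("pca") + 1:]:
            raise ConfigError(
                "matrix_corr may not follow pca: principal-component scores "
                "are mutually uncorrelated, so the correlation-matrix filter "
                "would be a guaranteed no-op")
        if self.rfe.model not in ("random_forest", "svm_radial"):
            raise ConfigError(f"unknown model '{self.rfe.model}'")
        if self.rfe.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.rfe.subset_sizes is not None:
            sizes = list(self.rfe.subset_sizes)
            if any(b <= a for a, b in zip(sizes, sizes[1:])) or any(
                    s < 1 for s in sizes):
                raise ConfigError(
                    "subset_sizes must be strictly increasing positive integers")
        return self

    def replace(self, **kw) -> "WorkflowConfig":
        return dataclasses.replace(self, **kw)


def validate_pair(X: FeatureMatrix, y: Outcome):
    """Check that a feature matrix and an outcome form a consistent pair.

    Idempotent and side-effect free; returns ``(X, y)`` unchanged.
    """
    if y.n_samples != X.n_samples:
        raise DimensionMismatchError(
            f"outcome length {y.n_samples} != {X.n_samples} samples")
    if y.task == CLASSIFICATION:
        levels, counts = np.unique(y.values.astype(str), return_counts=True)
        if len(levels) < 2:
            raise ClassSizeError(
                f"classification needs >= 2 class levels, got {len(levels)}")
        for lev, c in zip(levels, counts):
            if c < 2:
                raise ClassSizeError(f"class {lev} has < 2 samples")
    else:
        if not np.isfinite(y.values).all():
            raise ConstantOutcomeError("regression outcome has non-finite values")
        if np.ptp(y.values) == 0:
            raise ConstantOutcomeError("regression outcome is constant")
    return X, y


def drop_incomplete_features(X: FeatureMatrix):
    """Remove every feature with at least one missing (non-finite) cell.

    Mirrors complete-case gene filtering on expression matrices: only
    features observed in all samples enter the downstream filters.
    Idempotent. Returns ``(FeatureMatrix, FilterStepResult)``.
    """
    complete = np.isfinite(X.values).all(axis=0)
    kept = [f for f, ok in zip(X.feature_ids, complete) if ok]
    dropped = [f for f, ok in zip(X.feature_ids, complete) if not ok]
    if not kept:
        raise NoCompleteFeaturesError(
            "no complete features: every feature has a missing value")
    result = FilterStepResult(
        step_name="drop_incomplete",
        kept_feature_ids=kept,
        dropped_feature_ids=dropped,
        scores={},
        drop_reason={f: "missing_values" for f in dropped},
        cutoff=None,
    )
    return X.select_features(kept), result
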