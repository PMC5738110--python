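"""Univariate relevance filtering.

Two relevance scores are provided:

* absolute Pearson correlation of each feature with the outcome (the X2
  filter of the workflow) -- the outcome is the raw continuous value for
  regression, or a 0/1 encoding in ``class_levels`` order for binary
  classification;
* information gain in bits between the class and an equal-frequency
  discretization of the feature (classification only, any number of
  classes).

Features scoring at or below the cutoff are removed (the boundary itself
is dropped); for the redundancy filter the opposite convention holds, see
:mod:`omicsfs.multivariate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    CLASSIFICATION,
    FeatureMatrix,
    FilterStepResult,
    Outcome,
    validate_pair,
)
from .errors import EmptyFilterResultError, MultiClassCorrelationError, ValidationError


@dataclass
class UnivariateScoreVector:
    feature_ids: list[str]
    scores: np.ndarray
    method: str  # "pearson" | "information_gain"
    zero_variance: np.ndarray  # bool mask, aligned with feature_ids

    def as_dict(self) -> dict[str, float]:
        return {f: float(s) for f, s in zip(self.feature_ids, self.scores)}


def _outcome_numeric(y: Outcome) -> np.ndarray:
    if y.task == CLASSIFICATION and len(y.class_levels) > 2:
        raise MultiClassCorrelationError(
            f"correlation scoring is undefined for {len(y.class_levels)} "
            "classes; use the information-gain filter (univariate_gain) "
            "for multi-class outcomes")
    return y.numeric()


def correlation_scores(X: FeatureMatrix, y: Outcome) -> UnivariateScoreVector:
    """Absolute Pearson correlation of every feature with the outcome.

    Constant (zero-variance) features have an undefined correlation; they
    get score 0 and a ``zero_variance`` flag instead of raising, so
    degenerate omics columns never abort a run.
    """
    validate_pair(X, y)
    if not X.is_complete:
        raise ValidationError(
            "matrix has missing values; run drop_incomplete_features first")
    yv = _outcome_numeric(y)

    V = X.values
    xc = V - V.mean(axis=0)
    yc = yv - yv.mean()
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = math.sqrt(float((yc ** 2).sum()))
    zero_var = sx == 0.0
    denom = np.where(zero_var, 1.0, sx) * (sy if sy > 0 else 1.0)
    r = (xc * yc[:, None]).sum(axis=0) / denom
    scores = np.abs(r)
    scores[zero_var] = 0.0
    # numeric guard: |r| can exceed 1 by rounding
    np.clip(scores, 0.0, 1.0, out=scores)
    return UnivariateScoreVector(list(X.feature_ids), scores, "pearson",
                                 zero_var)


def filter_by_correlation(X: FeatureMatrix, y: Outcome,
                          cutoff: float = 0.30):
    """Drop every feature whose |Pearson r| with the outcome is <= cutoff.

    The boundary is removed (a score exactly equal to the cutoff falls),
    so ``cutoff=0.30`` keeps strictly ``|r| > 0.30``. Survivor order is
    the input column order.
    """
    sv = correlation_scores(X, y)
    return _apply_univariate(X, sv, cutoff, "univariate_corr")


def information_gain_scores(X: FeatureMatrix, y: Outcome,
                            n_bins: int | None = None) -> UnivariateScoreVector:
    """Information gain H(class) - H(class | binned feature), in bits.

    Each feature is discretized by equal-frequency binning with
    ``ceil(sqrt(n))`` bins capped at 10 (configurable via ``n_bins``).
    Constant features carry no information and score 0.
    """
    validate_pair(X, y)
    if y.task != CLASSIFICATION:
        raise ValidationError("information gain requires a classification task")
    if not X.is_complete:
        raise ValidationError(
            "matrix has missing values; run drop_incomplete_features first")
    n = X.n_samples
    if n_bins is None:
        n_bins = min(10, math.ceil(math.sqrt(n)))

    labels = np.asarray(y.values, dtype=object)
    _, y_codes = np.unique(labels.astype(str), return_inverse=True)
    h_class = _entropy_from_codes(y_codes)

    scores = np.empty(X.n_features)
    zero_var = np.zeros(X.n_features, dtype=bool)
    for j in range(X.n_features):
        col = X.values[:, j]
        if np.ptp(col) == 0:
            scores[j] = 0.0
            zero_var[j] = True
            continue
        bins = _equal_frequency_codes(col, n_bins)
        scores[j] = max(0.0, h_class - _conditional_entropy(y_codes, bins))
    return UnivariateScoreVector(list(X.feature_ids), scores,
                                 "information_gain", zero_var)


def filter_by_information_gain(X: FeatureMatrix, y: Outcome,
                               cutoff: float = 0.0,
                               n_bins: int | None = None):
    """Drop features whose information gain is <= cutoff (default: zero-gain)."""
    sv = information_gain_scores(X, y, n_bins=n_bins)
    return _apply_univariate(X, sv, cutoff, "univariate_gain")


def _apply_univariate(X: FeatureMatrix, sv: UnivariateScoreVector,
                      cutoff: float, step_name: str):
    keep_mask = sv.scores > cutoff
    kept = [f for f, k in zip(X.feature_ids, keep_mask) if k]
    if not kept:
        raise EmptyFilterResultError(
            f"no features pass the {step_name} filter at cutoff {cutoff} "
            f"(max score observed: {sv.scores.max():.6g})",
            max_score=float(sv.scores.max()))
    dropped = [f for f, k in zip(X.feature_ids, keep_mask) if not k]
    reason = {}
    for f, k, zv in zip(X.feature_ids, keep_mask, sv.zero_variance):
        if not k:
            reason[f] = "zero_variance" if zv else "below_cutoff"
    result = FilterStepResult(
        step_name=step_name,
        kept_feature_ids=kept,
        dropped_feature_ids=dropped,
        scores=sv.as_dict(),
        drop_reason=reason,
        cutoff=cutoff,
    )
    return X.select_features(kept), result


def _entropy_from_codes(codes: np.ndarray) -> float:
    counts = np.bincount(codes)
    p = counts[counts > 0] / len(codes)
    return float(-(p * np.log2(p)).sum())


def _conditional_entropy(y_codes: np.ndarray, bin_codes: np.ndarray) -> float:
    h = 0.0
    n = len(y_codes)
    for b in np.unique(bin_codes):
        mask = bin_codes == b
        h += mask.sum() / n * _entropy_from_codes(y_codes[mask])
    return h


def _equal_frequency_codes(col: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)  # tied quantiles collapse
    return np.searchsorted(edges, col, side="left")
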