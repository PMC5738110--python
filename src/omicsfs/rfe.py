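"""Recursive feature elimination wrapped around a learning model.

For each internal CV fold the features are ranked on the training part
only, the model is refit on the top-k features for every candidate subset
size, and the held-out part is scored. The chosen size maximizes mean CV
accuracy (classification) or minimizes mean CV RMSE (regression), ties
going to the smaller subset (parsimony). The final ranking and selection
are then computed on the full data.

Rankings: random forests use impurity-decrease importance; the radial-SVM
wrapper uses a model-free |Pearson r| ranking (permutation importance is
available behind ``importance="permutation"`` but is not the default, for
cost). Ties break by column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC, SVR

from .core import CLASSIFICATION, REGRESSION, FeatureMatrix, Outcome, validate_pair
from .errors import FoldConstructionError, MissingFeatureError, ValidationError
from .univariate import correlation_scores


@dataclass
class ModelSpec:
    """A wrapped learner: random forest or radial-kernel SVM."""

    kind: str = "random_forest"  # random_forest | svm_radial
    n_trees: int = 500
    svm_cost: float = 1.0
    svm_gamma: float | str = "median"  # median heuristic by default
    importance: str = "native"  # native | permutation

    def __post_init__(self):
        if self.kind not in ("random_forest", "svm_radial"):
            raise ValidationError(f"unknown model kind '{self.kind}'")
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if self.svm_cost <= 0:
            raise ValidationError("svm_cost must be > 0")


def _median_gamma(V: np.ndarray) -> float:
    """Radial-kernel width by the median heuristic on pairwise distances."""
    n = V.shape[0]
    if n > 200:  # subsample for cost; deterministic stride
        V = V[:: n // 200 + 1]
    d = pdist(V)
    d = d[d > 0]
    if len(d) == 0:
        return 1.0
    sigma = float(np.median(d))
    return 1.0 / (2.0 * sigma ** 2)


def build_estimator(model: ModelSpec, task: str, V: np.ndarray, seed: int):
    if model.kind == "random_forest":
        cls = (RandomForestClassifier if task == CLASSIFICATION
               else RandomForestRegressor)
        return cls(n_estimators=model.n_trees, random_state=seed, n_jobs=1)
    gamma = (_median_gamma(V) if model.svm_gamma == "median"
             else model.svm_gamma)
    if task == CLASSIFICATION:
        return SVC(C=model.svm_cost, kernel="rbf", gamma=gamma,
                   random_state=seed)
    return SVR(C=model.svm_cost, kernel="rbf", gamma=gamma)


def rank_features(model: ModelSpec, X: FeatureMatrix, y: Outcome,
                  seed: int = 0) -> list[str]:
    """Total importance order over features, most important first."""
    validate_pair(X, y)
    if model.kind == "svm_radial" and model.importance == "native":
        # model-free univariate ranking (binary/regression only)
        sv = correlation_scores(X, y)
        order = np.argsort(-sv.scores, kind="stable")
        return [X.feature_ids[i] for i in order]
    yv = y.values if y.task == CLASSIFICATION else y.values.astype(float)
    est = build_estimator(model, y.task, X.values, seed)
    est.fit(X.values, yv)
    if model.importance == "permutation":
        imp = permutation_importance(est, X.values, yv, n_repeats=5,
                                     random_state=seed).importances_mean
    else:
        imp = est.feature_importances_
    order = np.argsort(-imp, kind="stable")
    return [X.feature_ids[i] for i in order]


@dataclass
class RFEProfile:
    """Cross-validated performance profile over candidate subset sizes."""

    subset_sizes: list[int]
    cv_mean: np.ndarray    # accuracy fraction or RMSE, per size
    cv_sd: np.ndarray
    chosen_size: int
    final_ranking: list[str]
    selected_feature_ids: list[str]
    metric: str            # "accuracy" | "rmse"
    fold_rankings: list[list[str]] = field(default_factory=list)


def default_subset_sizes(n_features: int) -> list[int]:
    """Powers of two from 1 up to (and always including) n_features."""
    sizes = []
    k = 1
    while k < n_features:
        sizes.append(k)
        k *= 2
    sizes.append(n_features)
    return sizes


def _make_folds(y: Outcome, cv_folds: int, seed: int):
    n = y.n_samples
    if cv_folds > n:
        raise FoldConstructionError(
            f"cv_folds={cv_folds} exceeds n_samples={n}")
    if y.task == CLASSIFICATION:
        _, counts = np.unique(y.values.astype(str), return_counts=True)
        if counts.min() < cv_folds:
            raise FoldConstructionError(
                f"smallest class has {counts.min()} samples < cv_folds="
                f"{cv_folds}; use fewer folds")
        kf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                             random_state=seed)
        return list(kf.split(np.zeros(n), y.values.astype(str)))
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    return list(kf.split(np.zeros(n)))


def _score(est, V, y: Outcome) -> float:
    pred = est.predict(V)
    if y.task == CLASSIFICATION:
        return float(np.mean(pred == y.values))
    return float(np.sqrt(np.mean((pred - y.values) ** 2)))


def rfe(X: FeatureMatrix, y: Outcome, model: ModelSpec | None = None,
        cv_folds: int = 10, subset_sizes: list[int] | None = None,
        seed: int = 0) -> RFEProfile:
    """Backward feature elimination with internal k-fold cross-validation.

    Deterministic given the seed. Subset sizes exceeding the current
    feature count are pruned (with a warning from the caller's logger);
    the full count is always evaluated.
    """
    validate_pair(X, y)
    model = model or ModelSpec()
    p = X.n_features
    if subset_sizes is None:
        sizes = default_subset_sizes(p)
    else:
        sizes = sorted({s for s in subset_sizes if 1 <= s <= p})
        if not sizes:
            sizes = [p]
    folds = _make_folds(y, cv_folds, seed)

    per_fold = np.empty((len(folds), len(sizes)))
    fold_rankings: list[list[str]] = []
    for fi, (tr, te) in enumerate(folds):
        Xtr, ytr = X.select_samples(tr), y.select_samples(tr)
        Xte, yte = X.select_samples(te), y.select_samples(te)
        ranking = rank_features(model, Xtr, ytr, seed=seed + fi + 1)
        fold_rankings.append(ranking)
        for si, k in enumerate(sizes):
            top = ranking[:k]
            est = build_estimator(model, y.task,
                                  Xtr.select_features(top).values,
                                  seed + fi + 1)
            ytr_v = (ytr.values if y.task == CLASSIFICATION
                     else ytr.values.astype(float))
            est.fit(Xtr.select_features(top).values, ytr_v)
            per_fold[fi, si] = _score(est, Xte.select_features(top).values,
                                      yte)

    cv_mean = per_fold.mean(axis=0)
    cv_sd = per_fold.std(axis=0, ddof=1) if len(folds) > 1 else \
        np.zeros(len(sizes))
    if y.task == CLASSIFICATION:
        best = cv_mean.max()
        chosen = min(k for k, m in zip(sizes, cv_mean) if m >= best - 1e-12)
        metric = "accuracy"
    else:
        best = cv_mean.min()
        chosen = min(k for k, m in zip(sizes, cv_mean) if m <= best + 1e-12)
        metric = "rmse"

    final_ranking = rank_features(model, X, y, seed=seed)
    return RFEProfile(
        subset_sizes=sizes,
        cv_mean=cv_mean,
        cv_sd=cv_sd,
        chosen_size=chosen,
        final_ranking=final_ranking,
        selected_feature_ids=final_ranking[:chosen],
        metric=metric,
        fold_rankings=fold_rankings,
    )


@dataclass
class FittedModel:
    """A final model bound to named features; predicts by id matching."""

    estimator: object
    feature_ids: list[str]
    task: str
    training_metrics: dict[str, float]

    def predict(self, X: FeatureMatrix) -> np.ndarray:
        missing = [f for f in self.feature_ids if f not in set(X.feature_ids)]
        if missing:
            raise MissingFeatureError(missing)
        V = X.select_features(self.feature_ids).values
        return self.estimator.predict(V)


def fit_final_model(X: FeatureMatrix, y: Outcome,
                    model: ModelSpec | None = None,
                    seed: int = 0) -> FittedModel:
    """Fit the wrapped learner on the selected features; record train metrics."""
    from .workflow import compute_metrics  # local import to avoid a cycle

    validate_pair(X, y)
    model = model or ModelSpec()
    est = build_estimator(model, y.task, X.values, seed)
    yv = y.values if y.task == CLASSIFICATION else y.values.astype(float)
    est.fit(X.values, yv)
    metrics = compute_metrics(est.predict(X.values), y.values, y.task)
    return FittedModel(est, list(X.feature_ids), y.task, metrics)
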