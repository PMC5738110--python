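"""Multivariate redundancy reduction: CM elimination and PCA filtering.

The correlation-matrix (CM) filter greedily removes one member of every
feature pair whose absolute pairwise Pearson correlation reaches the
cutoff, keeping the original features. The PCA filter replaces features
with principal-component scores, retaining the smallest number of
components whose cumulative explained variance reaches a target fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FeatureMatrix, FilterStepResult
from .errors import ValidationError, ZeroVarianceError

#: components with explained-variance ratio below this are rank noise
RANK_TOL = 1e-12


def correlation_matrix_filter(X: FeatureMatrix, cutoff: float = 0.75):
    """Greedy pairwise-redundancy elimination at an |r| >= cutoff boundary.

    Repeatedly take the currently most-correlated violating pair and drop
    the member with the larger mean absolute correlation against all
    features still retained (ties within 1e-12 drop the later column).
    Guarantees that no retained pair has |r| >= cutoff; a feature in no
    violating pair is never dropped. Dropped features are tagged
    ``redundant_pair``.
    """
    if not X.is_complete:
        raise ValidationError(
            "matrix has missing values; run drop_incomplete_features first")
    if X.n_features < 2:
        result = FilterStepResult("matrix_corr", list(X.feature_ids), [], {},
                                  {}, cutoff)
        return X, result
    sd = X.values.std(axis=0)
    if (sd == 0).any():
        bad = [f for f, s in zip(X.feature_ids, sd) if s == 0]
        raise ZeroVarianceError(
            f"zero-variance features (undefined correlation): {bad}; "
            "remove them first (e.g. with a univariate filter)")

    C = np.abs(np.corrcoef(X.values, rowvar=False))
    np.fill_diagonal(C, 0.0)
    p = X.n_features
    active = np.ones(p, dtype=bool)
    dropped_order: list[int] = []

    while True:
        sub = np.where(active)[0]
        if len(sub) < 2:
            break
        Csub = C[np.ix_(sub, sub)]
        flat = int(np.argmax(Csub))
        i_s, j_s = divmod(flat, len(sub))
        if Csub[i_s, j_s] < cutoff:
            break
        i, j = int(sub[i_s]), int(sub[j_s])
        # mean |r| of each pair member against all other retained features
        mean_i = Csub[i_s].sum() / (len(sub) - 1)
        mean_j = Csub[j_s].sum() / (len(sub) - 1)
        if abs(mean_i - mean_j) <= 1e-12:
            victim = max(i, j)
        else:
            victim = i if mean_i > mean_j else j
        active[victim] = False
        dropped_order.append(victim)

    kept = [X.feature_ids[k] for k in range(p) if active[k]]
    dropped = [X.feature_ids[k] for k in dropped_order]
    # per-feature score: mean absolute correlation against all other inputs
    mean_abs = C.sum(axis=1) / (p - 1)
    result = FilterStepResult(
        step_name="matrix_corr",
        kept_feature_ids=kept,
        dropped_feature_ids=dropped,
        scores={f: float(m) for f, m in zip(X.feature_ids, mean_abs)},
        drop_reason={f: "redundant_pair" for f in dropped},
        cutoff=cutoff,
    )
    out = X.select_features(kept)
    # machine-check the contract on every call
    if len(kept) >= 2:
        Ck = np.abs(np.corrcoef(out.values, rowvar=False))
        np.fill_diagonal(Ck, 0.0)
        assert Ck.max() < cutoff, "CM filter post-condition violated"
    return out, result


@dataclass
class PCAProjection:
    """A fitted principal-component basis for the standardized matrix."""

    loadings: np.ndarray              # features x components
    explained_variance_ratio: np.ndarray
    n_retained: int
    means: np.ndarray
    sds: np.ndarray
    feature_ids: list[str]
    scale: bool = True

    def transform(self, X: FeatureMatrix, n_components: int | None = None
                  ) -> FeatureMatrix:
        """Project new samples (matched by feature id) onto the basis."""
        k = self.n_retained if n_components is None else n_components
        Xs = X.select_features(self.feature_ids)
        Z = (Xs.values - self.means) / self.sds
        scores = Z @ self.loadings[:, :k]
        return FeatureMatrix(scores, list(X.sample_ids),
                             [f"PC{i + 1}" for i in range(k)])


def pca_fit(X: FeatureMatrix, scale: bool = True) -> PCAProjection:
    """PCA of the column-centered (and by default unit-variance-scaled) matrix.

    Deterministic across platforms: each component's sign is fixed so that
    its largest-magnitude loading is positive. Constant columns are kept
    but standardized to all-zeros (they carry no variance). At most
    ``min(n_samples - 1, n_features)`` components have nonzero variance.
    """
    if not X.is_complete:
        raise ValidationError(
            "matrix has missing values; run drop_incomplete_features first")
    if X.n_samples < 3:
        raise ValidationError("PCA requires at least 3 samples")
    means = X.values.mean(axis=0)
    sds = X.values.std(axis=0, ddof=1)
    if (sds == 0).all():
        raise ValidationError("all features are constant; PCA is undefined")
    safe_sds = np.where(sds == 0, 1.0, sds)
    Z = (X.values - means) / (safe_sds if scale else 1.0)
    if not scale:
        safe_sds = np.ones_like(sds)

    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    var = s ** 2
    ratio = var / var.sum()
    ratio[ratio < RANK_TOL] = 0.0
    loadings = Vt.T
    # sign convention: largest-|loading| entry positive in each component
    for k in range(loadings.shape[1]):
        jmax = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[jmax, k] < 0:
            loadings[:, k] = -loadings[:, k]
    n_nonzero = int((ratio > 0).sum())
    return PCAProjection(loadings, ratio, n_nonzero, means, safe_sds,
                         list(X.feature_ids), scale=scale)


def cumulative_variance(p: PCAProjection) -> np.ndarray:
    """Partial sums of the explained-variance ratios (ends at 1)."""
    return np.cumsum(p.explained_variance_ratio)


def pca_filter(X: FeatureMatrix, var_retained: float = 0.95,
               scale: bool = True):
    """Replace features by the fewest components reaching ``var_retained``.

    Returns the n_samples x k score matrix (feature ids ``PC1..PCk``) and
    the fitted projection with ``n_retained = k``.
    """
    if not 0.0 < var_retained <= 1.0:
        raise ValidationError("var_retained must be in (0, 1]")
    proj = pca_fit(X, scale=scale)
    cum = cumulative_variance(proj)
    # tolerate rounding at the top of the spectrum
    k = int(np.searchsorted(cum, var_retained - 1e-9) + 1)
    k = min(k, proj.n_retained if proj.n_retained > 0 else 1)
    proj.n_retained = k
    return proj.transform(X), proj
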