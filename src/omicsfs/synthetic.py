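"""Synthetic omics-like data with informative / redundant / noise blocks.

The generator realizes the structure the workflow assumes: a small block
of outcome-informative features, a block of redundant copies that are
highly correlated with one informative parent each (star topology, so
"which feature proxies which" is checkable), and a large block of
irrelevant noise. Class-conditional distributions are Gaussian for
analytic tractability; a t(3) heavy-tail option exists for robustness
tests. Everything is fully determined by the seed.

Default sizes are the desk-scale study conditions used throughout the
test-bench: n=150 samples, 5 informative features at standardized effect
d=1.5, 10 redundant copies at rho=0.85, 300 noise features, balanced
binary classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CLASSIFICATION, REGRESSION, FeatureMatrix, Outcome
from .errors import ValidationError


@dataclass
class SyntheticSpec:
    n_samples: int = 150
    k_informative: int = 5
    k_redundant: int = 10
    k_noise: int = 300
    effect_size: float = 1.5          # standardized class-mean difference
    coefficients: list[float] | None = None  # regression beta (informative)
    redundancy_rho: float = 0.85      # target corr of a copy with its parent
    noise_sd: float = 1.0             # regression residual SD
    missing_fraction: float = 0.0
    class_proportions: tuple[float, ...] = (0.5, 0.5)
    heavy_tails: bool = False         # t(3) instead of Gaussian noise
    seed: int = 0

    def validate(self, task: str) -> "SyntheticSpec":
        if self.n_samples < 4:
            raise ValidationError("n_samples must be >= 4")
        if min(self.k_informative, self.k_redundant, self.k_noise) < 0:
            raise ValidationError("block sizes must be non-negative")
        if task == CLASSIFICATION and self.effect_size > 0 \
                and self.k_informative < 1:
            raise ValidationError(
                "effect_size > 0 requires k_informative >= 1")
        if self.k_redundant > 0 and self.k_informative < 1:
            raise ValidationError("redundancy requires k_informative >= 1")
        if not 0.0 <= self.redundancy_rho < 1.0:
            raise ValidationError("redundancy_rho must be in [0, 1)")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValidationError("missing_fraction must be in [0, 1)")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValidationError("class_proportions must sum to 1")
        return self


@dataclass
class GroundTruth:
    informative_ids: list[str]
    redundant_parent: dict[str, str]  # copy id -> parent id
    noise_ids: list[str]

    @property
    def redundant_ids(self) -> list[str]:
        return list(self.redundant_parent)

    def signal_groups(self) -> dict[str, set[str]]:
        """Each informative signal with its proxies (itself + its copies)."""
        groups = {f: {f} for f in self.informative_ids}
        for copy, parent in self.redundant_parent.items():
            groups[parent].add(copy)
        return groups


def _noise(rng: np.random.Generator, shape, heavy: bool) -> np.ndarray:
    if heavy:
        return rng.standard_t(3, size=shape) / np.sqrt(3.0)  # unit variance
    return rng.standard_normal(shape)


def _feature_names(spec: SyntheticSpec):
    info = [f"info{i + 1}" for i in range(spec.k_informative)]
    red = [f"red{i + 1}" for i in range(spec.k_redundant)]
    noise = [f"noise{i + 1}" for i in range(spec.k_noise)]
    return info, red, noise


def _redundant_block(rng, informative: np.ndarray, parent_sd: np.ndarray,
                     parent_mean: np.ndarray, spec: SyntheticSpec):
    """Copies mix the *standardized* parent with fresh noise so the
    population correlation with the parent is exactly rho even when the
    parent carries class structure (its marginal variance exceeds 1)."""
    n = informative.shape[0]
    rho = spec.redundancy_rho
    block = np.empty((n, spec.k_redundant))
    parents = []
    for i in range(spec.k_redundant):
        p = i % spec.k_informative
        parents.append(p)
        z = (informative[:, p] - parent_mean[p]) / parent_sd[p]
        block[:, i] = rho * z + np.sqrt(1 - rho ** 2) * _noise(
            rng, n, spec.heavy_tails)
    return block, parents


def make_classification_data(spec: SyntheticSpec | None = None,
                             seed: int | None = None):
    """Gaussian class-conditional data: informative feature j in class c is
    N(mu_c, 1) with adjacent class means separated by ``effect_size``.

    Returns ``(FeatureMatrix, Outcome, GroundTruth)``.
    """
    spec = spec or SyntheticSpec()
    if seed is not None:
        spec = SyntheticSpec(**{**spec.__dict__, "seed": seed})
    spec.validate(CLASSIFICATION)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    n_classes = len(spec.class_proportions)

    # deterministic class counts (largest remainder), then a seeded shuffle
    raw = np.asarray(spec.class_proportions) * n
    counts = np.floor(raw).astype(int)
    rem = np.argsort(-(raw - counts))
    for i in range(n - counts.sum()):
        counts[rem[i % n_classes]] += 1
    codes = np.repeat(np.arange(n_classes), counts)
    codes = codes[rng.permutation(n)]
    labels = np.asarray([f"C{c}" for c in codes], dtype=object)

    mu = codes[:, None] * spec.effect_size  # class c mean = c*d, unit SD
    informative = mu + _noise(rng, (n, spec.k_informative), spec.heavy_tails)

    # population moments of the parent mixture, for exact-rho mixing
    props = np.asarray(spec.class_proportions)
    mean_mu = float((props * np.arange(n_classes) * spec.effect_size).sum())
    var_mu = float((props * (np.arange(n_classes) * spec.effect_size
                             - mean_mu) ** 2).sum())
    parent_mean = np.full(spec.k_informative, mean_mu)
    parent_sd = np.full(spec.k_informative, np.sqrt(1.0 + var_mu))

    redundant, parents = _redundant_block(rng, informative, parent_sd,
                                          parent_mean, spec)
    noise = _noise(rng, (n, spec.k_noise), spec.heavy_tails)

    values = np.hstack([informative, redundant, noise])
    info_ids, red_ids, noise_ids = _feature_names(spec)
    if spec.missing_fraction > 0:
        mask = rng.random(values.shape) < spec.missing_fraction
        values = values.copy()
        values[mask] = np.nan

    X = FeatureMatrix(values, [f"s{i + 1}" for i in range(n)],
                      info_ids + red_ids + noise_ids)
    y = Outcome(CLASSIFICATION, labels,
                class_levels=[f"C{c}" for c in range(n_classes)])
    gt = GroundTruth(info_ids,
                     {red_ids[i]: info_ids[parents[i]]
                      for i in range(spec.k_redundant)},
                     noise_ids)
    return X, y, gt


def make_regression_data(spec: SyntheticSpec | None = None,
                         seed: int | None = None):
    """Linear-model data: y = X_informative @ beta + N(0, noise_sd^2).

    ``coefficients`` defaults to all ones over the informative block.
    Returns ``(FeatureMatrix, Outcome, GroundTruth)``.
    """
    spec = spec or SyntheticSpec()
    if seed is not None:
        spec = SyntheticSpec(**{**spec.__dict__, "seed": seed})
    spec.validate(REGRESSION)
    beta = np.asarray(spec.coefficients if spec.coefficients is not None
                      else np.ones(spec.k_informative), dtype=float)
    if len(beta) != spec.k_informative:
        raise ValidationError(
            f"coefficient vector length {len(beta)} != k_informative "
            f"{spec.k_informative}")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples

    informative = _noise(rng, (n, spec.k_informative), spec.heavy_tails)
    yv = informative @ beta + rng.normal(0.0, spec.noise_sd, size=n)

    parent_mean = np.zeros(spec.k_informative)
    parent_sd = np.ones(spec.k_informative)
    redundant, parents = _redundant_block(rng, informative, parent_sd,
                                          parent_mean, spec)
    noise = _noise(rng, (n, spec.k_noise), spec.heavy_tails)

    values = np.hstack([informative, redundant, noise])
    info_ids, red_ids, noise_ids = _feature_names(spec)
    if spec.missing_fraction > 0:
        mask = rng.random(values.shape) < spec.missing_fraction
        values = values.copy()
        values[mask] = np.nan

    X = FeatureMatrix(values, [f"s{i + 1}" for i in range(n)],
                      info_ids + red_ids + noise_ids)
    y = Outcome(REGRESSION, yv)
    gt = GroundTruth(info_ids,
                     {red_ids[i]: info_ids[parents[i]]
                      for i in range(spec.k_redundant)},
                     noise_ids)
    return X, y, gt


def recovered_signal_fraction(selected_ids, gt: GroundTruth) -> float:
    """Fraction of informative signals represented in a selection,
    counting a signal as recovered if the feature itself or any of its
    redundant copies was selected."""
    sel = set(selected_ids)
    groups = gt.signal_groups()
    if not groups:
        return 1.0
    hit = sum(1 for proxies in groups.values() if proxies & sel)
    return hit / len(groups)
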