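"""Desk-scale benchmark harnesses built from the package's own pieces.

These drive the canonical X2 -> CM -> RFE-RF pipeline on the synthetic
informative/redundant/noise family (the generator defaults) and report
recovery and non-inferiority summaries. Problem sizes are chosen to run
on a single CPU in minutes: 3-fold internal CV and 100-tree forests, as
documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FilterStep, RFEConfig, WorkflowConfig
from .synthetic import SyntheticSpec, make_classification_data, recovered_signal_fraction
from .workflow import evaluate_workflow, run_workflow

#: desk-scale wrapped-forest settings for simulation loops
BENCH_RFE = dict(cv_folds=3, model_options={"n_trees": 100})


def x2_cm_rfe_rf_config(seed: int = 0) -> WorkflowConfig:
    """The full filter+wrapper pipeline at its published cutoffs."""
    return WorkflowConfig(
        task="classification",
        steps=[FilterStep("univariate_corr", 0.30),
               FilterStep("matrix_corr", 0.75)],
        rfe=RFEConfig(**BENCH_RFE),
        seed=seed,
    )


def rf_baseline_config(seed: int = 0) -> WorkflowConfig:
    """Random forest with no feature selection at all."""
    return WorkflowConfig(
        task="classification", steps=[],
        rfe=RFEConfig(enabled=False,
                      model_options={"n_trees": 100}),
        seed=seed,
    )


@dataclass
class RecoveryResult:
    n_seeds: int
    per_seed_recovery: list[float]
    per_seed_n_selected: list[int]

    @property
    def fraction_seeds_recovering_80pct(self) -> float:
        return float(np.mean([r >= 0.8 for r in self.per_seed_recovery]))

    @property
    def mean_recovery(self) -> float:
        return float(np.mean(self.per_seed_recovery))


def recovery_simulation(n_seeds: int = 100, base_seed: int = 0,
                        spec: SyntheticSpec | None = None) -> RecoveryResult:
    """Run the full pipeline over seeded replicates of the synthetic
    family and score how many informative signals are represented in the
    final selection (a redundant copy counts as its parent's proxy)."""
    recov, counts = [], []
    for i in range(n_seeds):
        seed = int(np.random.SeedSequence([int(base_seed), i]).generate_state(
            1)[0] % (2 ** 31))
        spec_i = spec or SyntheticSpec()
        X, y, gt = make_classification_data(spec_i, seed=seed)
        result = run_workflow(X, y, x2_cm_rfe_rf_config(seed=seed))
        recov.append(recovered_signal_fraction(result.final_feature_ids, gt))
        counts.append(len(result.final_feature_ids))
    return RecoveryResult(n_seeds, recov, counts)


@dataclass
class NonInferiorityResult:
    fs_mean_accuracy: float
    fs_sd: float
    baseline_mean_accuracy: float
    baseline_sd: float
    median_selected_fraction: float
    n_splits: int

    @property
    def accuracy_gap(self) -> float:
        """FS minus no-FS mean accuracy (positive favors selection)."""
        return self.fs_mean_accuracy - self.baseline_mean_accuracy


def non_inferiority_evaluation(seed: int = 0, n_splits: int = 20,
                               spec: SyntheticSpec | None = None
                               ) -> NonInferiorityResult:
    """Compare the full pipeline against a no-selection forest over
    repeated stratified splits of one synthetic dataset."""
    spec = spec or SyntheticSpec()
    X, y, _ = make_classification_data(spec, seed=seed)
    fs = evaluate_workflow(X, y, x2_cm_rfe_rf_config(seed=seed),
                           n_splits=n_splits, seed=seed)
    base = evaluate_workflow(X, y, rf_baseline_config(seed=seed),
                             n_splits=n_splits, seed=seed)
    frac = np.median(fs.per_split_n_features) / X.n_features
    return NonInferiorityResult(
        fs_mean_accuracy=fs.mean["accuracy"],
        fs_sd=fs.sd["accuracy"],
        baseline_mean_accuracy=base.mean["accuracy"],
        baseline_sd=base.sd["accuracy"],
        median_selected_fraction=float(frac),
        n_splits=n_splits,
    )
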