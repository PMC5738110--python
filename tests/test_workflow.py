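import numpy as np
import pytest

from omicsfs import (
    FeatureMatrix,
    Outcome,
    RFEConfig,
    SyntheticSpec,
    WorkflowConfig,
    compute_metrics,
    compute_metrics_ss,
    evaluate_workflow,
    make_classification_data,
    recovered_signal_fraction,
    run_workflow,
)
from omicsfs.core import FilterStep
from omicsfs.errors import ConfigError, StepError

FAST_RFE = dict(cv_folds=3, model_options={"n_trees": 60})


def _x2_cm_rfe_config(seed=0):
    return WorkflowConfig(
        task="classification",
        steps=[FilterStep("univariate_corr"), FilterStep("matrix_corr")],
        rfe=RFEConfig(**FAST_RFE),
        seed=seed,
    )


class TestComputeMetrics:
    def test_perfect_regression_prediction(self):
        m = compute_metrics([1.0, 2, 3], [1.0, 2, 3], "regression")
        assert m["rmse"] == 0.0 and m["r2"] == pytest.approx(1.0)

    def test_all_wrong_binary_predictions(self):
        m = compute_metrics(["A", "A"], ["B", "B"], "classification")
        assert m["accuracy"] == 0.0

    def test_five_point_fixture_matches_hand_computation(self):
        # RMSE = sqrt(0.3), R^2 = squared Pearson r, both worked out from
        # the defining formulas by hand
        pred = [1.0, 2.0, 3.0, 4.0, 5.0]
        obs = [1.5, 2.0, 2.5, 4.0, 6.0]
        m = compute_metrics(pred, obs, "regression")
        assert m["rmse"] == pytest.approx(0.5477225575051661, abs=1e-12)
        assert m["r2"] == pytest.approx(0.9097744360902255, abs=1e-12)

    def test_constant_predictions_flagged_r2_zero(self):
        with pytest.warns(UserWarning, match="constant predictions"):
            m = compute_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0],
                                "regression")
        assert m["r2"] == 0.0 and m["r2_undefined"] == 1.0

    def test_ss_convention_differs_from_correlation_convention(self):
        pred = [2.0, 3.0, 4.0, 5.0, 6.0]  # biased but perfectly correlated
        obs = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert compute_metrics(pred, obs, "regression")["r2"] == \
            pytest.approx(1.0)
        assert compute_metrics_ss(pred, obs)["r2"] < 1.0


class TestRunWorkflow:
    def test_identity_pipeline_keeps_all_features(self, synth_classification):
        X, y, _ = synth_classification
        config = WorkflowConfig(task="classification", steps=[],
                                rfe=RFEConfig(enabled=False,
                                              model_options={"n_trees": 30}))
        result = run_workflow(X, y, config)
        assert result.final_feature_ids == X.feature_ids

    def test_forbidden_step_order_fails_before_computation(self,
                                                           synth_classification):
        X, y, _ = synth_classification
        with pytest.raises(ConfigError, match="uncorrelated"):
            run_workflow(X, y, WorkflowConfig(
                task="classification",
                steps=[FilterStep("pca"), FilterStep("matrix_corr")]))

    def test_feature_counts_non_increasing(self, synth_classification):
        X, y, _ = synth_classification
        result = run_workflow(X, y, _x2_cm_rfe_config(seed=1))
        counts = result.n_features_per_step
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        assert counts[0] == X.n_features
        assert counts[-1] == len(result.final_feature_ids)

    def test_step_error_names_offending_step(self):
        rng = np.random.default_rng(0)
        V = np.column_stack([rng.standard_normal(20), np.full(20, 1.0)])
        X = FeatureMatrix(V, [f"s{i}" for i in range(20)], ["f1", "f2"])
        y = Outcome("classification", ["A", "B"] * 10)
        config = WorkflowConfig(task="classification",
                                steps=[FilterStep("matrix_corr")],
                                rfe=RFEConfig(enabled=False))
        with pytest.raises(StepError, match="matrix_corr"):
            run_workflow(X, y, config)

    def test_recovery_of_informative_signals(self):
        spec = SyntheticSpec(n_samples=120, k_informative=5, k_redundant=10,
                             k_noise=200, effect_size=2.0,
                             redundancy_rho=0.9, seed=7)
        X, y, gt = make_classification_data(spec)
        result = run_workflow(X, y, _x2_cm_rfe_config(seed=7))
        signal_ids = set(gt.informative_ids) | set(gt.redundant_ids)
        selected = set(result.final_feature_ids)
        # the selection is dominated by true signal proxies; an occasional
        # lucky noise feature may survive the univariate screen
        assert len(selected - signal_ids) <= 1
        assert recovered_signal_fraction(result.final_feature_ids, gt) >= 0.8

    def test_missing_values_trigger_complete_case_step(self):
        spec = SyntheticSpec(n_samples=80, k_informative=3, k_redundant=0,
                             k_noise=20, effect_size=2.0,
                             missing_fraction=0.02, seed=13)
        X, y, _ = make_classification_data(spec)
        config = WorkflowConfig(task="classification",
                                steps=[FilterStep("univariate_corr")],
                                rfe=RFEConfig(enabled=False,
                                              model_options={"n_trees": 30}))
        result = run_workflow(X, y, config)
        assert result.steps[0].step_name == "drop_incomplete"
        assert all(r == "missing_values"
                   for r in result.steps[0].drop_reason.values())

    def test_pca_pipeline_predicts_on_new_samples(self):
        spec = SyntheticSpec(n_samples=90, k_informative=3, k_redundant=0,
                             k_noise=40, effect_size=2.5, seed=17)
        X, y, _ = make_classification_data(spec)
        tr = np.arange(60)
        te = np.arange(60, 90)
        config = WorkflowConfig(
            task="classification",
            steps=[FilterStep("univariate_corr"), FilterStep("pca")],
            rfe=RFEConfig(**FAST_RFE), seed=3)
        result = run_workflow(X.select_samples(tr), y.select_samples(tr),
                              config)
        pred = result.predict(X.select_samples(te))
        acc = float(np.mean(pred == y.values[te]))
        assert acc > 0.8


class TestEvaluateWorkflow:
    def test_separable_data_reaches_perfect_accuracy(self):
        spec = SyntheticSpec(n_samples=80, k_informative=3, k_redundant=0,
                             k_noise=10, effect_size=8.0, seed=23)
        X, y, _ = make_classification_data(spec)
        summary = evaluate_workflow(X, y, _x2_cm_rfe_config(seed=23),
                                    n_splits=5)
        assert summary.mean["accuracy"] == pytest.approx(1.0)

    def test_null_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(31)
        spec = SyntheticSpec(n_samples=90, k_informative=1, k_redundant=0,
                             k_noise=15, effect_size=0.0,
                             class_proportions=(0.6, 0.4), seed=31)
        X, y, _ = make_classification_data(spec)
        config = WorkflowConfig(task="classification", steps=[],
                                rfe=RFEConfig(enabled=False,
                                              model_options={"n_trees": 60}),
                                seed=31)
        summary = evaluate_workflow(X, y, config, n_splits=10)
        majority = 0.6
        n_test = 30
        sd_null = np.sqrt(majority * (1 - majority) / n_test)
        assert abs(summary.mean["accuracy"] - majority) < 3 * sd_null

    def test_same_seed_reproduces_summary_exactly(self, synth_classification):
        X, y, _ = synth_classification
        config = _x2_cm_rfe_config(seed=2)
        a = evaluate_workflow(X, y, config, n_splits=4)
        b = evaluate_workflow(X, y, config, n_splits=4)
        assert a.per_split_metrics == b.per_split_metrics
        assert a.per_split_selected == b.per_split_selected
        assert a.mean == b.mean and a.sd == b.sd

    def test_summary_moments_match_per_split_vector(self, synth_classification):
        X, y, _ = synth_classification
        summary = evaluate_workflow(X, y, _x2_cm_rfe_config(seed=5),
                                    n_splits=4)
        accs = [m["accuracy"] for m in summary.per_split_metrics]
        assert summary.mean["accuracy"] == pytest.approx(np.mean(accs),
                                                         abs=1e-12)
        assert summary.sd["accuracy"] == pytest.approx(np.std(accs, ddof=1),
                                                       abs=1e-12)

    def test_selection_depends_only_on_training_rows(self,
                                                     synth_classification):
        """Perturbing each split's held-out rows must not change the
        features selected by that split's training phase."""
        X, y, _ = synth_classification
        config = _x2_cm_rfe_config(seed=8)
        summary = evaluate_workflow(X, y, config, n_splits=3)
        from omicsfs.workflow import split_seed

        for i, tr in enumerate(summary.per_split_train_idx):
            te = np.setdiff1d(np.arange(X.n_samples), tr)
            V = X.values.copy()
            V[te] = 1e6 * np.random.default_rng(i).standard_normal(
                V[te].shape)
            Xc = FeatureMatrix(V, X.sample_ids, X.feature_ids)
            result = run_workflow(Xc.select_samples(tr),
                                  y.select_samples(tr),
                                  config.replace(seed=split_seed(8, i)))
            assert result.final_feature_ids == summary.per_split_selected[i]

    def test_downsample_balance_mode_runs(self):
        spec = SyntheticSpec(n_samples=90, k_informative=2, k_redundant=0,
                             k_noise=10, effect_size=2.0,
                             class_proportions=(0.7, 0.3), seed=3)
        X, y, _ = make_classification_data(spec)
        config = WorkflowConfig(task="classification",
                                steps=[FilterStep("univariate_corr")],
                                rfe=RFEConfig(enabled=False,
                                              model_options={"n_trees": 30}),
                                seed=3)
        summary = evaluate_workflow(X, y, config, n_splits=3,
                                    balance="downsample")
        assert summary.n_splits == 3
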