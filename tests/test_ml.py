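"""Decision-tree feature selection, stability, k-fold ensemble evaluation."""

import numpy as np
import pandas as pd
import pytest

import csfpanel as cp
from csfpanel.ml import MLConfig, fit_decision_tree, tree_feature_order

from conftest import make_matrix


def frame(arr, feature_names=None):
    arr = np.asarray(arr, dtype=float)
    names = feature_names or [f"f{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=names)


class TestPrepareFeatureTable:
    def test_zero_imputation_of_missing(self):
        m = make_matrix([[1.0, np.nan], [0.5, -0.5]], scale=cp.Scale.LOG10)
        labels = pd.Series(["AD", "non_AD"], index=m.samples)
        X, y = cp.prepare_feature_table(m, m.protein_ids, labels, impute_zero=True)
        assert X.loc["s1", "P000"] == 0.0
        X2, _ = cp.prepare_feature_table(m, m.protein_ids, labels, impute_zero=False)
        assert np.isnan(X2.loc["s1", "P000"])

    def test_contracts(self):
        m = make_matrix([[1.0, 2.0]], scale=cp.Scale.LOG10)
        labels = pd.Series(["AD", "non_AD"], index=m.samples)
        with pytest.raises(ValueError):
            cp.prepare_feature_table(m, [], labels)
        with pytest.raises(KeyError):
            cp.prepare_feature_table(m, ["nope"], labels)


class TestDecisionTree:
    def test_threshold_separable_depth_one(self):
        X = frame([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = [0, 0, 0, 1, 1, 1]
        depth, features, accs = cp.min_depth_for_full_training_accuracy(X, y)
        assert depth == 1 and features == ["f0"] and accs[1] == 1.0

    def test_xor_needs_depth_two(self):
        X = frame([[0, 0], [0, 1], [1, 0], [1, 1]] * 3)
        y = [0, 1, 1, 0] * 3
        depth, _, accs = cp.min_depth_for_full_training_accuracy(X, y)
        assert depth == 2
        assert accs[1] < 1.0

    def test_pure_input_single_leaf(self):
        X = frame([[1.0], [2.0]])
        tree = fit_decision_tree(X, [1, 1])
        assert tree.tree_.children_left[0] == -1

    def test_conflicting_duplicates_raise_at_cap(self):
        X = frame([[1.0], [1.0]])
        with pytest.raises(ValueError, match="0.5"):
            cp.min_depth_for_full_training_accuracy(X, [0, 1], depth_max_cap=3)

    def test_determinism_same_seed_same_tree(self):
        rng = np.random.default_rng(0)
        X = frame(rng.normal(size=(50, 5)))
        y = (X["f2"] > 0).astype(int)
        t1 = fit_decision_tree(X, y, seed=3)
        t2 = fit_decision_tree(X, y, seed=3)
        assert np.array_equal(t1.tree_.feature, t2.tree_.feature)
        assert np.array_equal(t1.tree_.threshold, t2.tree_.threshold)

    def test_feature_order_root_first(self):
        rng = np.random.default_rng(1)
        X = frame(rng.normal(size=(100, 4)))
        y = ((X["f1"] > 0) & (X["f3"] > 0)).astype(int)
        tree = fit_decision_tree(X, y, max_depth=3, seed=0)
        order = tree_feature_order(tree, list(X.columns))
        assert order[0] == [f"f{i}" for i in tree.tree_.feature][0]


class TestRankStability:
    def test_separable_feature_always_root(self):
        X = frame([[0.0, 5.0], [1.0, -3.0], [2.0, 2.2], [10.0, 1.0], [11.0, -2.0], [12.0, 0.1]])
        y = [0, 0, 0, 1, 1, 1]
        stab = cp.feature_rank_stability(X, y, n_repeats=50, seed=0)
        assert stab.loc["f0", "rank1_freq"] == 1.0

    def test_duplicated_features_split_root_frequency(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=80)
        y = (a > 0).astype(int)
        X = frame(np.column_stack([a, a]), feature_names=["dup1", "dup2"])
        stab = cp.feature_rank_stability(X, y, n_repeats=100, seed=0)
        total = stab["rank1_freq"].sum()
        assert total == pytest.approx(1.0)
        assert stab["rank1_freq"].max() < 1.0  # ties shared between duplicates

    def test_single_repeat_frequencies_binary(self):
        X = frame([[0.0], [1.0], [5.0], [6.0]])
        stab = cp.feature_rank_stability(X, [0, 0, 1, 1], n_repeats=1, seed=0)
        assert set(stab["rank1_freq"]) <= {0.0, 1.0}


class TestRocAuc:
    def test_worked_example(self):
        (_, _), auc = cp.roc_auc([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0])
        assert auc == pytest.approx(0.75)

    def test_perfect_and_tied_scores(self):
        assert cp.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])[1] == 1.0
        assert cp.roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])[1] == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            cp.roc_auc([0.1, 0.2], [1, 1])

    def test_matches_all_pairs_concordance_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = int(rng.integers(10, 200))
            scores = np.round(rng.uniform(size=n), 2)  # ties likely
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            _, auc = cp.roc_auc(scores, labels)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            oracle = sum(
                1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
            ) / (len(pos) * len(neg))
            assert auc == pytest.approx(oracle, abs=0)


class TestConfusionMetrics:
    def test_printed_counts_reproduce_metrics(self):
        sens, spec, acc = cp.confusion_metrics(72, 16, 95, 14)
        assert sens == pytest.approx(0.8182, abs=5e-5)
        assert spec == pytest.approx(0.8716, abs=5e-5)
        assert acc == pytest.approx(0.8477, abs=5e-5)

    def test_degenerate_cases(self):
        assert cp.confusion_metrics(10, 0, 10, 0) == (1.0, 1.0, 1.0)
        assert cp.confusion_metrics(0, 10, 10, 0) == (0.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            cp.confusion_metrics(0, 0, 5, 5)


class TestKFoldEvaluate:
    def test_separable_data_perfect_metrics(self):
        rng = np.random.default_rng(5)
        n = 60
        x = np.concatenate([rng.normal(-4, 0.3, n // 2), rng.normal(4, 0.3, n // 2)])
        X = frame(np.column_stack([x, rng.normal(size=n)]))
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        report = cp.kfold_evaluate(X, y, config=MLConfig(k_folds=4, seed=0))
        assert report.mean_auc == pytest.approx(1.0)
        assert report.accuracy == pytest.approx(1.0)

    def test_test_folds_partition_samples(self):
        rng = np.random.default_rng(6)
        X = frame(rng.normal(size=(48, 3)))
        y = rng.integers(0, 2, 48)
        report = cp.kfold_evaluate(X, y, config=MLConfig(k_folds=6, seed=1))
        assert report.tp + report.fn + report.tn + report.fp == 48
        assert report.tp + report.fn == int(y.sum())

    def test_permuted_labels_auc_near_half(self):
        rng = np.random.default_rng(7)
        X = frame(rng.normal(size=(197, 6)))
        y = rng.permutation([1] * 88 + [0] * 109)
        report = cp.kfold_evaluate(X, y, config=MLConfig(k_folds=6, seed=2))
        assert 0.4 <= report.mean_auc <= 0.6

    def test_xgboost_backend_pluggable(self):
        rng = np.random.default_rng(12)
        n = 60
        x = np.concatenate([rng.normal(-3, 0.5, n // 2), rng.normal(3, 0.5, n // 2)])
        X = frame(np.column_stack([x, rng.normal(size=n)]))
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        report = cp.kfold_evaluate(
            X, y, config=MLConfig(k_folds=4, seed=0, backend="xgboost")
        )
        # tiny folds + early stopping can leave slight underfit; near-perfect
        # separation is what the backend contract guarantees here
        assert report.mean_auc >= 0.95

    def test_string_labels_use_ad_as_positive(self):
        rng = np.random.default_rng(8)
        n = 40
        x = np.concatenate([rng.normal(-3, 0.5, 20), rng.normal(3, 0.5, 20)])
        X = frame(x[:, None])
        y = np.array(["non_AD"] * 20 + ["AD"] * 20)
        report = cp.kfold_evaluate(X, y, config=MLConfig(k_folds=4, seed=0))
        assert report.tp + report.fn == 20  # the AD class is the positive one


class TestIterativeFeatureAddition:
    def test_single_informative_feature_selected_first(self):
        rng = np.random.default_rng(9)
        n = 80
        informative = np.concatenate([rng.normal(-3, 0.5, 40), rng.normal(3, 0.5, 40)])
        X = frame(np.column_stack([informative] + [rng.normal(size=n) for _ in range(3)]))
        y = np.array([0] * 40 + [1] * 40)
        aucs, selected = cp.iterative_feature_addition(
            X, y, ["f0", "f1", "f2", "f3"], MLConfig(k_folds=4, seed=0, plateau_epsilon=0.01)
        )
        assert selected == 1
        assert aucs[1] == pytest.approx(1.0)

    def test_large_epsilon_selects_one(self):
        rng = np.random.default_rng(10)
        X = frame(rng.normal(size=(40, 3)))
        y = rng.integers(0, 2, 40)
        _, selected = cp.iterative_feature_addition(
            X, y, list(X.columns), MLConfig(k_folds=4, seed=0, plateau_epsilon=1.0)
        )
        assert selected == 1


class TestEndToEndPanel:
    def test_simulated_study_panel_performance(
        self, sim_log_bundle, sim_labels, sim_truth
    ):
        """Panel selection and evaluation on the simulated cohorts.

        The tau-like protein should dominate the tree root and the boosted
        ensemble should separate AD from non-AD well.
        """
        z = cp.zscore(sim_log_bundle.matrix, sim_log_bundle.metadata, "within_cohort")
        X, y = cp.prepare_feature_table(z, z.protein_ids, sim_labels)
        y_bin = (y == "AD").to_numpy().astype(int)
        depth, features, _ = cp.min_depth_for_full_training_accuracy(X, y_bin, seed=0)
        assert features[0] == sim_truth.mapt_protein_id
        stab = cp.feature_rank_stability(X[features], y_bin, n_repeats=200, seed=0)
        assert stab.loc[sim_truth.mapt_protein_id, "rank1_freq"] >= 0.95
        report = cp.kfold_evaluate(X, y_bin, features, MLConfig(k_folds=6, seed=0))
        assert report.mean_auc >= 0.85
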