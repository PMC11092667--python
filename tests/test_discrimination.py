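"""SVM identification experiment: splits, classifiers, statistics."""

import numpy as np
import pandas as pd
import pytest

from gaitsig.cohort import CohortConfig, generate_cohort
from gaitsig.discrimination import (
    baseline_discrete_experiment,
    compare_accuracy_distributions,
    filter_complete_subjects,
    permuted_label_accuracy,
    speed_generalization_experiment,
    split_trials,
    train_identify_svm,
)
from gaitsig.preprocess import compute_discrete_variables, detect_gait_events
from tests.conftest import make_cluster_table


class TestFilterCompleteSubjects:
    def test_study_layout_retains_14(self):
        # 17 subjects x 9 trials with 3 trials missing across 3 subjects
        rows = []
        for i in range(17):
            n = 8 if i < 3 else 9
            for j in range(n):
                rows.append({"subject_id": f"S{i:02d}", "trial_id": f"{i}_{j}"})
        table = pd.DataFrame(rows)
        out = filter_complete_subjects(table, required_trials=9)
        assert out["subject_id"].nunique() == 14

    def test_all_complete_is_identity(self):
        table = make_cluster_table(4, 5)
        out = filter_complete_subjects(table, required_trials=5)
        assert len(out) == len(table)

    def test_unreachable_requirement_raises(self):
        table = make_cluster_table(3, 4)
        with pytest.raises(ValueError, match="no subject"):
            filter_complete_subjects(table, required_trials=99)


class TestSplitTrials:
    def test_k8_of_9_leaves_one_test_trial_per_subject(self):
        table = make_cluster_table(5, 9)
        train, test = split_trials(table, k_train=8, seed=1)
        assert len(test) == 5
        assert table.iloc[test]["subject_id"].nunique() == 5

    def test_same_seed_identical_split(self):
        table = make_cluster_table(4, 6)
        a = split_trials(table, 3, seed=7)
        b = split_trials(table, 3, seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_uniform_test_membership_over_seeds(self):
        # each of a subject's 9 trials lands in test with frequency (9-k)/9
        table = make_cluster_table(3, 9)
        k = 4
        counts = np.zeros(len(table))
        n_seeds = 140
        for seed in range(n_seeds):
            _, test = split_trials(table, k, seed=seed)
            counts[test] += 1
        freq = counts / n_seeds
        np.testing.assert_allclose(freq, (9 - k) / 9, atol=0.1)

    def test_out_of_range_k_rejected(self):
        table = make_cluster_table(3, 5)
        for bad in (0, 5, 9):
            with pytest.raises(ValueError, match="k_train"):
                split_trials(table, bad, seed=0)


class TestTrainIdentifySVM:
    def test_separable_subjects_classified_perfectly(self):
        table = make_cluster_table(2, 6, separation=50.0, noise=0.1, seed=1)
        res = speed_generalization_experiment(table, k_range=[3], n_runs=5)
        assert res[0].mean_accuracy == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            train_identify_svm(np.zeros((5, 3)), np.array(["a"] * 5))

    def test_duplicated_columns_leave_predictions_unchanged(self):
        table = make_cluster_table(3, 6, dim=10, seed=2)
        feats = [c for c in table.columns if c.startswith("v")]
        train, test = split_trials(table, 3, seed=3)
        X = table[feats].to_numpy()
        y = table["subject_id"].to_numpy()
        sc1, clf1 = train_identify_svm(X[train], y[train])
        Xd = np.hstack([X, X])
        sc2, clf2 = train_identify_svm(Xd[train], y[train])
        p1 = clf1.predict(sc1.transform(X[test]))
        p2 = clf2.predict(sc2.transform(Xd[test]))
        np.testing.assert_array_equal(p1, p2)

    def test_leakage_guard_test_rows_do_not_affect_classifier(self):
        table = make_cluster_table(3, 6, seed=4)
        feats = [c for c in table.columns if c.startswith("v")]
        train, test = split_trials(table, 3, seed=5)
        X = table[feats].to_numpy()
        y = table["subject_id"].to_numpy()
        _, clf1 = train_identify_svm(X[train], y[train])
        X_pert = X.copy()
        X_pert[test] += 100.0  # only test rows perturbed
        _, clf2 = train_identify_svm(X_pert[train], y[train])
        np.testing.assert_array_equal(clf1.dual_coef_, clf2.dual_coef_)
        np.testing.assert_array_equal(clf1.intercept_, clf2.intercept_)


class TestExperiment:
    def test_identical_signatures_give_chance_accuracy(self):
        table = make_cluster_table(5, 6, separation=0.0, noise=0.0, seed=0)
        res = speed_generalization_experiment(table, k_range=[3], n_runs=10)
        assert res[0].mean_accuracy == pytest.approx(1 / 5, abs=0.05)

    def test_accuracy_non_decreasing_in_k(self):
        table = make_cluster_table(6, 8, separation=2.0, noise=1.5, seed=6)
        res = speed_generalization_experiment(table, k_range=[1, 3, 6],
                                              n_runs=25)
        means = [r.mean_accuracy for r in res]
        assert means[1] >= means[0] - 0.02
        assert means[2] >= means[1] - 0.02

    def test_determinism_of_full_experiment(self):
        table = make_cluster_table(4, 6, seed=8)
        r1 = speed_generalization_experiment(table, k_range=[2], n_runs=6)
        r2 = speed_generalization_experiment(table, k_range=[2], n_runs=6)
        np.testing.assert_array_equal(r1[0].accuracies, r2[0].accuracies)

    def test_permuted_labels_collapse_to_chance(self):
        table = make_cluster_table(5, 6, separation=10.0, noise=0.5, seed=9)
        accs = permuted_label_accuracy(table, k_train=3, n_runs=50, seed=0)
        chance = 1 / 5
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(accs.mean() - chance) < 3 * max(se, 1e-3)


class TestCompareAccuracyDistributions:
    def test_identical_samples_null_result(self):
        a = np.array([0.5, 0.6, 0.7, 0.8])
        u, p, r = compare_accuracy_distributions(a, a.copy())
        assert p > 0.9
        assert abs(r) < 0.05

    def test_fully_shifted_large_effect(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.5, 0.05, 30)
        u, p, r = compare_accuracy_distributions(a + 10, a)
        assert p < 1e-6
        assert r > 0.5

    def test_hand_computed_u(self):
        # {1,2,3} vs {4,5,6}: no pair with a > b, so U of the first
        # sample is 0 (scipy convention: statistic of sample a)
        u, p, r = compare_accuracy_distributions(
            np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]))
        assert u == 0.0
        assert r < 0


class TestBaselineDiscrete:
    @pytest.fixture(scope="class")
    def discrete_tables(self):
        cfg = CohortConfig(
            n_subjects=4, speeds_per_subject=4, speed_min=0.6, speed_max=1.6,
            duration_s=10.0, data_type="combined", seed=13,
        )
        trials, meta = generate_cohort(cfg)
        tables = {}
        for set_name in ("biomech26", "spatiotemporal10"):
            rows = []
            for (trial, truth), (_, m) in zip(trials, meta.iterrows()):
                ev = detect_gait_events(trial.vgrf_right, trial.vgrf_left,
                                        trial.fs)
                row = {"trial_id": m["trial_id"],
                       "subject_id": m["subject_id"], "speed": m["speed"]}
                row.update(compute_discrete_variables(
                    trial, ev, set_name, step_width=truth.true_step_width))
                rows.append(row)
            tables[set_name] = pd.DataFrame(rows)
        return tables

    def test_biomech_beats_spatiotemporal(self, discrete_tables):
        res = baseline_discrete_experiment(discrete_tables, k_range=[2],
                                           n_runs=10)
        acc_bio = res["biomech26"][0].mean_accuracy
        acc_st = res["spatiotemporal10"][0].mean_accuracy
        assert acc_bio > acc_st

    def test_one_hot_features_are_perfectly_separable(self):
        rows = []
        for i in range(4):
            for j in range(5):
                row = {"trial_id": f"{i}_{j}", "subject_id": f"S{i}",
                       "speed": 1.0}
                row.update({f"v{k}": float(k == i) for k in range(4)})
                rows.append(row)
        table = pd.DataFrame(rows)
        res = speed_generalization_experiment(table, k_range=[2], n_runs=5)
        assert res[0].mean_accuracy == 1.0
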