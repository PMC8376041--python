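"""LDA staging: separation, invariances, validation schemes, permutation tests."""

import numpy as np
import pytest

from embryograd.staging import (
    STAGE_ORDER,
    evaluate,
    fit_lda,
    predict_stage,
    subgroup_trajectory,
)
from embryograd.staging import test_group_difference as group_difference_test
from embryograd.synthetic import SUBGROUPS


def gaussian_clusters(centers, n, seed=0, sd=1.0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(c, sd, size=(n, len(c))) for c in centers])
    y = np.repeat([f"g{i}" for i in range(len(centers))], n)
    return X, y


class TestFitPredict:
    def test_well_separated_class_means_classified_correctly(self):
        X, y = gaussian_clusters([np.zeros(4), np.full(4, 10.0)], 20, seed=1)
        clf = fit_lda(X, y)
        for mean, label in zip(clf.class_means, clf.labels):
            pred, _ = predict_stage(clf, mean)
            assert pred == label

    def test_affine_invariance_of_predictions(self):
        X, y = gaussian_clusters(
            [np.zeros(4), np.full(4, 3.0), np.array([3, 0, 3, 0.0])], 30, seed=2
        )
        rng = np.random.default_rng(3)
        A = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        b = rng.standard_normal(4)
        p1, _ = predict_stage(fit_lda(X, y), X)
        p2, _ = predict_stage(fit_lda(X @ A + b, y), X @ A + b)
        assert np.mean(p1 == p2) > 0.99

    def test_three_clusters_4sd_apart_loo_accuracy(self):
        # Monte-Carlo check of expected leave-one-out accuracy over seeds
        centers = [np.zeros(4), np.array([4, 0, 0, 0.0]), np.array([0, 4, 0, 0.0])]
        accs = [
            evaluate(*gaussian_clusters(centers, 50, seed=s), scheme="loo").accuracy
            for s in range(10)
        ]
        assert np.mean(accs) >= 0.95

    def test_missing_features_rejected_in_predict(self):
        X, y = gaussian_clusters([np.zeros(4), np.full(4, 10.0)], 20, seed=4)
        clf = fit_lda(X, y)
        with pytest.raises(ValueError):
            predict_stage(clf, np.array([1.0, np.nan, 0.0, 0.0]))

    def test_nan_rows_excluded_from_fit(self):
        X, y = gaussian_clusters([np.zeros(4), np.full(4, 10.0)], 20, seed=5)
        X[0, 3] = np.nan
        clf = fit_lda(X, y)
        assert clf.class_means.shape == (2, 4)

    def test_tie_broken_by_developmental_order(self):
        rng = np.random.default_rng(6)
        half = rng.standard_normal((30, 2))
        X = np.vstack([half + [0, 0], half + [4, 0], half + [2, 5]])
        y = np.repeat(["cleavage", "syncytial", "cc14"], 30)
        clf = fit_lda(X, y)
        assert clf.labels == STAGE_ORDER
        # exactly between the first two class means, far from the third:
        mid = 0.5 * (clf.class_means[0] + clf.class_means[1])
        pred, scores = predict_stage(clf, mid)
        assert abs(scores[0] - scores[1]) < 1e-9
        assert pred == "cleavage"  # earlier stage wins the tie

    def test_too_small_class_rejected(self):
        X = np.zeros((6, 4))
        y = np.array(["a"] * 4 + ["b"] * 2, dtype=object)
        with pytest.raises(ValueError):
            fit_lda(X, y)


class TestEvaluate:
    def test_perfectly_separable_loo_all_correct(self):
        X, y = gaussian_clusters(
            [np.zeros(4), np.full(4, 50.0), np.full(4, 100.0)], 10, seed=7
        )
        cm = evaluate(X, y, scheme="loo")
        np.testing.assert_array_equal(cm.per_class_correct, 1.0)
        assert cm.n == 30

    def test_permuted_labels_accuracy_no_better_than_chance(self):
        X, y = gaussian_clusters([np.zeros(4), np.zeros(4)], 40, seed=8)
        cm = evaluate(X, y, scheme="loo")
        # indistinguishable classes: no signal above chance (leave-one-out is
        # pessimistically biased on null data, so only the upper side holds)
        assert cm.accuracy <= 0.5 + 3 * np.sqrt(0.25 / cm.n)
        cm_r = evaluate(X, y, scheme="resubstitution")
        assert abs(cm_r.accuracy - 0.5) < 3 * np.sqrt(0.25 / cm_r.n)

    def test_resubstitution_not_worse_than_loo_on_average(self):
        # classic optimism property of in-sample evaluation
        centers = [np.zeros(4), np.full(4, 1.5)]
        diffs = []
        for s in range(50):
            X, y = gaussian_clusters(centers, 15, seed=100 + s)
            r = evaluate(X, y, scheme="resubstitution").accuracy
            l = evaluate(X, y, scheme="loo").accuracy
            diffs.append(r - l)
        assert np.mean(diffs) >= 0.0

    def test_synthetic_three_stage_cohort_majority_correct(self, cohort_features):
        feats, labels = cohort_features
        cm = evaluate(feats, labels, scheme="loo")
        assert np.all(cm.per_class_correct > 0.5)

    def test_kfold_scheme_runs(self, cohort_features):
        feats, labels = cohort_features
        cm = evaluate(feats, labels, scheme="kfold")
        assert cm.n > 0 and np.all(cm.per_class_correct > 0.5)


class TestTrajectory:
    def test_identical_members_reproduce_group_features(self):
        X = np.tile(np.arange(4.0), (18, 1)) + np.repeat(
            np.arange(9.0)[:, None], 2, axis=0
        )
        g = np.repeat(list(SUBGROUPS), 2)
        traj = subgroup_trajectory(X, g)
        assert list(traj.index) == list(SUBGROUPS)
        np.testing.assert_allclose(
            traj["lambda1_apical"].to_numpy(), np.arange(9.0)
        )

    def test_single_record_per_subgroup(self):
        X = np.arange(36.0).reshape(9, 4)
        traj = subgroup_trajectory(X, np.array(list(SUBGROUPS), dtype=object))
        np.testing.assert_allclose(traj[traj.columns[1:]].to_numpy(), X)

    def test_empty_subgroup_omitted(self):
        X = np.zeros((4, 4))
        g = np.array(["cc10", "cc10", "cc11", "cc11"], dtype=object)
        traj = subgroup_trajectory(X, g)
        assert list(traj.index) == ["cc10", "cc11"]

    def test_preset_cohort_lambda1_monotone_through_cc13(self):
        from embryograd import compute_features, fit_profile, generate_cohort
        from embryograd.synthetic import NoiseSpec, stage_preset

        # zero between-embryo spread and mild noise: the fitted trajectory
        # must reproduce the presets' monotone lambda1 ordering exactly
        presets = [
            type(p)(name=p.name, means=p.means, c0_log_sd=0.0, alpha_log_sd=0.0)
            for p in (stage_preset(n) for n in SUBGROUPS[:6])
        ]
        recs = generate_cohort(presets, 3, seed=11, noise=NoiseSpec(additive_sd=0.5))
        feats, groups = [], []
        for r in recs:
            fa = fit_profile(r.apical, "2exp", (10, 90))
            fb = fit_profile(r.basal, "2exp", (10, 90))
            feats.append(compute_features(fa, fb, r.embryo_id))
            groups.append(r.subgroup)
        traj = subgroup_trajectory(feats, np.array(groups, dtype=object))
        lam = traj["lambda1_apical"].to_numpy()
        assert np.all(np.diff(lam) > 0)


class TestGroupDifference:
    def test_identical_groups_give_large_p(self):
        X = np.tile(np.arange(4.0), (40, 1))
        y = np.repeat(["a", "b"], 20)
        p = group_difference_test(X, y, n_perm=300, seed=0)
        assert (p >= 0.5).all()

    def test_separated_groups_give_tiny_p(self):
        X, y = gaussian_clusters([np.zeros(4), np.full(4, 5.0)], 30, seed=9)
        p = group_difference_test(X, y, n_perm=10000, seed=1)
        assert p["omnibus"] <= 0.001
        assert (p.drop("omnibus") <= 0.001).all()

    def test_same_seed_identical_p_values(self):
        X, y = gaussian_clusters([np.zeros(4), np.ones(4)], 15, seed=10)
        p1 = group_difference_test(X, y, n_perm=500, seed=3)
        p2 = group_difference_test(X, y, n_perm=500, seed=3)
        assert (p1 == p2).all()

    def test_low_n_perm_warns(self):
        X, y = gaussian_clusters([np.zeros(4), np.ones(4)], 10, seed=11)
        with pytest.warns(UserWarning):
            group_difference_test(X, y, n_perm=50, seed=0)

    def test_type_i_error_controlled_on_null(self):
        # null cohorts: rejection rate at alpha=0.05 within binomial slack
        rejections = 0
        trials = 60
        for s in range(trials):
            X, y = gaussian_clusters([np.zeros(2), np.zeros(2)], 12, seed=500 + s)
            p = group_difference_test(X, y, n_perm=200, seed=s)
            rejections += p["omnibus"] <= 0.05
        rate = rejections / trials
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / trials)
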