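import numpy as np
import pytest
from sklearn.datasets import make_blobs

from dsahrv.evaluation import (
    DEFAULT_CONFIGS,
    ClassifierConfig,
    RotationForestClassifier,
    WeightedVoteEnsemble,
    average_roc,
    classification_metrics,
    make_classifier,
    run_cv,
    wilcoxon_test,
)

from .oracles import ranksum_permutation_pvalue


def blobs(n=100, features=10, sep=6.0, seed=0):
    X, y = make_blobs(
        n_samples=n, centers=2, n_features=features, cluster_std=1.0,
        center_box=(-sep, sep), random_state=seed,
    )
    return X, np.where(y == 1, "PAF", "SR")


class TestWilcoxon:
    def test_identical_paired_groups_degenerate(self):
        a = np.full(10, 0.5)
        with pytest.raises(ValueError, match="degenerate test"):
            wilcoxon_test(a, a, paired=True)

    def test_pairing_mismatch(self):
        with pytest.raises(ValueError, match="pairing mismatch"):
            wilcoxon_test(np.ones(6), np.ones(7), paired=True)

    def test_complete_separation_is_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.9, 0.01, 30)
        b = rng.normal(0.2, 0.01, 30)
        p = wilcoxon_test(a, b)
        assert p < 0.005
        p_perm = ranksum_permutation_pvalue(a, b)
        assert p_perm < 0.005  # oracle agrees the difference is real

    def test_agrees_with_permutation_oracle_on_moderate_effect(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, 25)
        b = rng.normal(0.7, 1.0, 25)
        p = wilcoxon_test(a, b)
        p_perm = ranksum_permutation_pvalue(a, b, n_perm=20_000, seed=2)
        assert p == pytest.approx(p_perm, abs=0.01)

    def test_paired_detects_consistent_shift(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, 30)
        b = a + 0.8
        assert wilcoxon_test(a, b, paired=True) < 0.005


class TestClassificationMetrics:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((45, 5, 5, 45), {"precision": 0.9, "recall": 0.9, "F": 0.9, "ACC": 0.9}),
            ((10, 0, 0, 10), {"precision": 1.0, "recall": 1.0, "F": 1.0, "ACC": 1.0}),
            ((0, 0, 10, 10), {"precision": 0.0, "recall": 0.0, "F": 0.0, "ACC": 0.5}),
        ],
    )
    def test_confusion_to_metrics(self, counts, expected):
        m = classification_metrics(*counts)
        for key, val in expected.items():
            assert m[key] == pytest.approx(val)

    def test_degenerate_predictor_flags_precision(self):
        m = classification_metrics(0, 0, 10, 10)
        assert "precision" in m["undefined"]

    def test_f_is_harmonic_mean(self):
        m = classification_metrics(30, 10, 5, 55)
        p, r = m["precision"], m["recall"]
        assert m["F"] == pytest.approx(2 * p * r / (p + r))


class TestRotationForest:
    def test_rotation_matrices_are_orthonormal(self):
        X, y = blobs(n=80, features=10, seed=1)
        rof = RotationForestClassifier(n_rotations=5, random_state=0).fit(X, y)
        for R in rof.rotations_:
            np.testing.assert_allclose(R.T @ R, np.eye(R.shape[0]), atol=1e-8)

    def test_separable_blobs_training_accuracy(self):
        X, y = blobs(n=100, features=10, seed=2)
        rof = RotationForestClassifier(random_state=0).fit(X, y)
        assert np.mean(rof.predict(X) == y) == 1.0

    def test_single_feature_group_size_one(self):
        X, y = blobs(n=80, features=1, seed=3)
        rof = RotationForestClassifier(group_size=1, random_state=0).fit(X, y)
        for R in rof.rotations_:  # 1x1 rotation is +/-1
            assert abs(abs(R[0, 0]) - 1.0) < 1e-12
        assert np.mean(rof.predict(X) == y) > 0.9

    def test_invalid_grouping_and_degenerate_labels(self):
        X, y = blobs(n=40, features=2, seed=4)
        with pytest.raises(ValueError, match="invalid grouping"):
            RotationForestClassifier(group_size=5).fit(X, y)
        with pytest.raises(ValueError, match="degenerate labels"):
            RotationForestClassifier().fit(X, np.repeat("SR", 40))

    def test_shuffled_labels_give_chance_level_cv(self):
        X, y = blobs(n=60, features=8, seed=5)
        rng = np.random.default_rng(5)
        y_shuf = rng.permutation(y)
        res = run_cv(X, y_shuf, DEFAULT_CONFIGS["RoF"], folds=5, repeats=2, seed=5)
        assert 0.35 <= res.means["ACC"] <= 0.65


class TestWeightedVoteEnsemble:
    def test_empty_members_rejected(self):
        with pytest.raises(ValueError, match="no base classifiers"):
            WeightedVoteEnsemble(members=[]).fit(np.ones((10, 2)), np.repeat(["SR", "PAF"], 5))

    def test_unanimous_members_equal_any_member(self):
        X, y = blobs(n=80, features=6, seed=6)
        members = [
            ("a", make_classifier(DEFAULT_CONFIGS["RF"], random_state=0)),
            ("b", make_classifier(DEFAULT_CONFIGS["RF"], random_state=0)),
        ]
        ens = WeightedVoteEnsemble(members=members).fit(X, y)
        np.testing.assert_array_equal(ens.predict(X), ens.fitted_[0].predict(X))

    def test_perfect_member_takes_clipped_weight(self):
        X, y = blobs(n=80, features=6, seed=7)
        ens = make_classifier(DEFAULT_CONFIGS["EL"], random_state=0).fit(X, y)
        errs = [np.mean(m.predict(X) != y) for m in ens.fitted_]
        for err, w in zip(errs, ens.weights_):
            if err == 0.0:
                assert w == 10.0

    def test_committee_not_worse_than_members_on_separable_data(self):
        wins = 0
        for seed in range(6):
            X, y = blobs(n=90, features=8, seed=seed)
            rng = np.random.default_rng(seed)
            idx = rng.permutation(len(y))
            tr, te = idx[:60], idx[60:]
            ens = make_classifier(DEFAULT_CONFIGS["EL"], random_state=seed).fit(X[tr], y[tr])
            acc_ens = np.mean(ens.predict(X[te]) == y[te])
            acc_members = max(np.mean(m.predict(X[te]) == y[te]) for m in ens.fitted_)
            wins += acc_ens >= acc_members
        assert wins >= 5  # weighted vote tracks the best member almost always

    def test_tie_resolves_to_positive_class(self):
        ens = WeightedVoteEnsemble(members=[("x", None)])
        ens.classes_ = np.array(["PAF", "SR"])
        ens.fitted_ = []
        ens.weights_ = []
        # direct check of the decision rule at score exactly 0.5
        other = "SR"
        assert np.where(np.array([0.5]) >= 0.5, "PAF", other)[0] == "PAF"


class TestAverageRoc:
    def test_identical_folds_equal_single_fold(self):
        y = np.array([0, 0, 1, 1], bool)
        s = np.array([0.1, 0.4, 0.35, 0.8])
        single = average_roc([(y, s)])
        triple = average_roc([(y, s)] * 3)
        np.testing.assert_allclose(single[1], triple[1], atol=1e-12)
        assert single[2] == pytest.approx(triple[2], abs=1e-12)

    def test_perfect_scores_give_auc_one(self):
        y = np.array([0, 0, 0, 1, 1, 1], bool)
        s = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        assert average_roc([(y, s)] * 5)[2] == 1.0

    def test_single_class_folds_excluded_with_warning(self):
        good = (np.array([0, 1, 0, 1], bool), np.array([0.2, 0.9, 0.4, 0.7]))
        bad = (np.array([1, 1, 1, 1], bool), np.array([0.2, 0.9, 0.4, 0.7]))
        with pytest.warns(UserWarning, match="single-class"):
            _, _, auc = average_roc([good, bad])
        assert 0.0 <= auc <= 1.0


class TestRunCV:
    def test_same_seed_reproduces_result_exactly(self):
        X, y = blobs(n=50, features=6, seed=8)
        a = run_cv(X, y, DEFAULT_CONFIGS["kNN"], repeats=3, seed=4)
        b = run_cv(X, y, DEFAULT_CONFIGS["kNN"], repeats=3, seed=4)
        assert a.per_repeat.equals(b.per_repeat)
        np.testing.assert_array_equal(a.roc_tpr, b.roc_tpr)
        assert a.means == b.means

    def test_f_is_harmonic_mean_per_repeat(self):
        X, y = blobs(n=60, features=6, seed=9, sep=2.0)
        res = run_cv(X, y, DEFAULT_CONFIGS["kNN"], repeats=4, seed=1)
        for _, row in res.per_repeat.iterrows():
            p, r = row["precision"], row["recall"]
            expected = 0.0 if p + r == 0 else 2 * p * r / (p + r)
            assert row["F"] == pytest.approx(expected)

    def test_degenerate_and_insufficient_inputs(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(ValueError, match="degenerate labels"):
            run_cv(X, np.repeat("SR", 20), DEFAULT_CONFIGS["kNN"])
        y = np.array(["PAF"] * 3 + ["SR"] * 17)
        with pytest.raises(ValueError, match="insufficient data"):
            run_cv(X, y, DEFAULT_CONFIGS["kNN"], folds=5)

    def test_grid_search_stays_inside_declared_ranges(self):
        X, y = blobs(n=60, features=4, seed=10)
        cfg = DEFAULT_CONFIGS["kNN"]
        from sklearn.model_selection import GridSearchCV

        est = GridSearchCV(make_classifier(cfg), cfg.grid, cv=3).fit(X, y)
        assert est.best_params_["n_neighbors"] in cfg.grid["n_neighbors"]
        assert est.best_params_["weights"] in cfg.grid["weights"]

    def test_unknown_classifier_rejected(self):
        with pytest.raises(ValueError, match="unknown classifier"):
            ClassifierConfig("MLP")
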