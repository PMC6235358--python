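import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from vtwarn.classify import (
    EvalConfig,
    balance_by_undersampling,
    mann_whitney_u,
    permutation_importance,
    roc_auc,
    run_evaluation,
    sensitivity_specificity,
    split_train_test,
    train_linear_svm,
    train_random_forest,
)
from vtwarn.records import PRE_SHOCK, REGULAR, RRValidationError


def _rows(n_reg, n_pre, rng=None, n_features=0):
    rng = rng or np.random.default_rng(0)
    n = n_reg + n_pre
    data = {
        "record_id": [f"r{i}" for i in range(n)],
        "patient_id": [f"p{i % max(2, n // 6)}" for i in range(n)],
        "label": [REGULAR] * n_reg + [PRE_SHOCK] * n_pre,
    }
    for j in range(n_features):
        data[f"f{j}"] = rng.standard_normal(n)
    return pd.DataFrame(data)


def _toy_separable(rng, n=60):
    y = np.arange(n) % 2 == 0
    X = rng.standard_normal((n, 2)) * 0.2
    X[y, 0] += 4.0
    return X, y


class TestBalance:
    def test_undersamples_majority_to_minority(self):
        balanced = balance_by_undersampling(_rows(666, 23), rng_seed=1)
        counts = balanced["label"].value_counts()
        assert counts[REGULAR] == 23 and counts[PRE_SHOCK] == 23
        # minority kept whole
        assert set(balanced.loc[balanced.label == PRE_SHOCK, "record_id"]) == set(
            _rows(666, 23).loc[lambda d: d.label == PRE_SHOCK, "record_id"]
        )

    def test_balanced_input_unchanged(self):
        rows = _rows(30, 30)
        assert balance_by_undersampling(rows, 3) is rows

    def test_deterministic_given_seed(self):
        a = balance_by_undersampling(_rows(100, 10), 7)
        b = balance_by_undersampling(_rows(100, 10), 7)
        pd.testing.assert_frame_equal(a, b)
        c = balance_by_undersampling(_rows(100, 10), 8)
        assert not a["record_id"].equals(c["record_id"])

    def test_single_class_rejected(self):
        with pytest.raises(RRValidationError):
            balance_by_undersampling(_rows(10, 0), 0)


class TestSplit:
    def test_partition_is_disjoint_and_exhaustive(self):
        rows = _rows(40, 40)
        train, test = split_train_test(rows, 0.8, 1)
        assert len(train) + len(test) == len(rows)
        assert set(train.record_id).isdisjoint(test.record_id)
        for label, grp in train.groupby("label"):
            assert len(grp) == round(0.8 * 40)

    def test_same_seed_same_split(self):
        rows = _rows(50, 50)
        t1, _ = split_train_test(rows, 0.8, 9)
        t2, _ = split_train_test(rows, 0.8, 9)
        pd.testing.assert_frame_equal(t1, t2)

    def test_patient_grouped_split_never_straddles(self):
        rows = _rows(60, 60)
        train, test = split_train_test(rows, 0.8, 2, group_by_patient=True)
        assert set(train.patient_id).isdisjoint(test.patient_id)

    def test_tiny_class_rejected(self):
        with pytest.raises(RRValidationError):
            split_train_test(_rows(10, 3), 0.8, 0)


class TestClassifiers:
    def test_forest_fits_separable_data(self):
        rng = np.random.default_rng(0)
        X, y = _toy_separable(rng)
        model = train_random_forest(X, y, 1, n_trees=100)
        assert (model.predict(X) == y).all()
        np.testing.assert_array_equal(
            model.score(X), train_random_forest(X, y, 1, n_trees=100).score(X)
        )

    def test_svm_separates_with_margins(self):
        rng = np.random.default_rng(1)
        X, y = _toy_separable(rng)
        model = train_linear_svm(X, y, 1)
        margins = model.score(X)
        assert (margins[y] > 0).all() and (margins[~y] < 0).all()

    def test_svm_standardizes_with_training_stats_only(self):
        rng = np.random.default_rng(2)
        X, y = _toy_separable(rng, n=40)
        model = train_linear_svm(X, y, 0)
        np.testing.assert_allclose(model.scaler.mean_, X.mean(axis=0))
        np.testing.assert_allclose(model.scaler.scale_, X.std(axis=0))

    @pytest.mark.parametrize("trainer", [train_random_forest, train_linear_svm])
    def test_permuted_labels_give_chance_auc(self, trainer):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((120, 4))
            y = rng.permutation(np.arange(120) % 2 == 0)
            kwargs = {"n_trees": 50} if trainer is train_random_forest else {}
            model = trainer(X[:80], y[:80], seed, **kwargs)
            aucs.append(roc_auc(model.score(X[80:]), y[80:]))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)

    def test_single_class_training_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(RRValidationError):
            train_random_forest(X, np.ones(10, dtype=bool), 0)
        with pytest.raises(RRValidationError):
            train_linear_svm(X, np.zeros(10, dtype=bool), 0)


class TestROC:
    def test_perfect_ranking(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 10, [True] * 5 + [False] * 5) == 0.5

    def test_matches_pair_counting_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            scores = rng.normal(size=20).round(1)  # rounding forces some ties
            labels = rng.random(20) < 0.4
            if labels.all() or not labels.any():
                continue
            pos, neg = scores[labels], scores[~labels]
            concordant = sum(
                1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
            )
            oracle = concordant / (pos.size * neg.size)
            assert roc_auc(scores, labels) == pytest.approx(oracle, abs=1e-12)
            assert roc_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores)
            )

    def test_label_flip_complements_auc(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        assert roc_auc(scores, labels) == pytest.approx(1.0 - roc_auc(scores, ~labels))

    def test_one_class_rejected(self):
        with pytest.raises(RRValidationError):
            roc_auc([0.1, 0.2], [True, True])


class TestSensitivitySpecificity:
    def test_all_correct(self):
        assert sensitivity_specificity([True, False], [True, False]) == (1.0, 1.0)

    def test_everything_positive(self):
        assert sensitivity_specificity([True] * 4, [True, True, False, False]) == (1.0, 0.0)

    def test_two_by_two_arithmetic(self):
        labels = [True] * 4 + [False] * 4  # TP=3 FN=1 TN=2 FP=2
        preds = [True, True, True, False, True, True, False, False]
        assert sensitivity_specificity(preds, labels) == (0.75, 0.5)


class TestPermutationImportance:
    def _forest_with_signal(self, seed, n=150):
        rng = np.random.default_rng(seed)
        y = rng.random(n) < 0.5
        X = rng.standard_normal((n, 3))
        X[:, 0] += np.where(y, 3.0, -3.0)  # only predictor 0 is informative
        model = train_random_forest(X, y, seed, n_trees=100)
        return model, X, y

    def test_oob_masks_reproduce_sklearn_bootstrap(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((80, 3))
        y = rng.random(80) < 0.5
        clf = RandomForestClassifier(
            n_estimators=50, oob_score=True, random_state=1, n_jobs=1
        ).fit(X, y)
        from vtwarn.classify import _bootstrap_oob_masks

        votes = np.zeros((80, 2))
        for tree, oob in zip(clf.estimators_, _bootstrap_oob_masks(clf, 80)):
            votes[oob] += tree.predict_proba(X[oob])
        mine = votes[:, 1] / votes.sum(axis=1)
        oob_acc = np.mean((mine > 0.5) == y)
        assert oob_acc == pytest.approx(clf.oob_score_, abs=1e-12)

    def test_informative_predictor_ranks_first(self):
        model, X, y = self._forest_with_signal(1)
        imp = permutation_importance(model, X, y, 0)
        assert imp.argmax() == 0

    def test_noise_predictors_near_zero(self):
        vals = []
        for seed in range(20):
            model, X, y = self._forest_with_signal(seed)
            imp = permutation_importance(model, X, y, seed)
            vals.extend(imp[1:])
        assert np.max(np.abs(vals)) < 0.02


class TestMannWhitney:
    def test_identical_groups_null(self):
        t = mann_whitney_u([1.0, 2.0, 3.0, 4.0] * 6, [1.0, 2.0, 3.0, 4.0] * 6)
        assert t.p_value >= 0.9

    def test_exact_small_sample(self):
        t = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert t.u_statistic == 0.0
        assert t.p_value == pytest.approx(0.1, abs=1e-12)
        assert t.median_a == 2.0 and t.median_b == 5.0

    def test_normal_approximation_close_to_exact(self):
        checked = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.normal(0.0, 1.0, 9)
            b = rng.normal(0.5, 1.0, 9)
            approx = mann_whitney_u(a, b).p_value  # n=9 -> asymptotic path
            exact = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            if exact < 0.01:
                continue  # the normal tail is known to be off in deep tails
            checked += 1
            assert approx == pytest.approx(exact, rel=0.10)
        assert checked >= 5

    def test_empty_group_rejected(self):
        with pytest.raises(RRValidationError):
            mann_whitney_u([], [1.0])


class TestRunEvaluation:
    @pytest.fixture()
    def small_problem(self):
        rng = np.random.default_rng(12)
        n_reg, n_pre, m = 40, 30, 200
        rows = _rows(n_reg, n_pre)
        windows = 0.8 + 0.04 * rng.standard_normal((n_reg + n_pre, m))
        windows[n_reg:] -= 0.08  # pre-shock records beat faster
        for f in ("alpha1", "alpha2", "mean_nn", "bp1", "bp2", "bp3", "bp4", "bp5",
                  "hjorth_complexity", "hjorth_mobility"):
            rows[f] = rng.standard_normal(len(rows))
        rows.loc[rows.label == PRE_SHOCK, "alpha2"] -= 1.0
        return rows, windows

    def test_single_trial_matches_manual_pass(self, small_problem):
        rows, windows = small_problem
        cfg = EvalConfig(n_trials=1, seed=3, classifiers=("random_forest",),
                         n_trees=50, compute_importance=False)
        res = run_evaluation(rows, windows, cfg)
        res2 = run_evaluation(rows, windows, cfg)
        assert res.per_trial == res2.per_trial
        assert res.aggregate["random_forest"]["auc"]["sd"] == 0.0

    def test_aggregate_equals_mean_of_trials(self, small_problem):
        rows, windows = small_problem
        cfg = EvalConfig(n_trials=4, seed=3, classifiers=("random_forest", "linear_svm"),
                         n_trees=50, compute_importance=False)
        res = run_evaluation(rows, windows, cfg)
        frame = pd.DataFrame(res.per_trial)
        for clf in cfg.classifiers:
            sel = frame[frame.classifier == clf]
            for metric in ("sensitivity", "specificity", "auc"):
                assert res.aggregate[clf][metric]["mean"] == pytest.approx(
                    sel[metric].mean(), abs=1e-12
                )
        assert all(
            0.0 <= t[m] <= 1.0 for t in res.per_trial
            for m in ("sensitivity", "specificity", "auc")
        )

    def test_importance_names_follow_predictor_order(self, small_problem):
        rows, windows = small_problem
        cfg = EvalConfig(n_trials=1, seed=0, classifiers=("random_forest",), n_trees=30)
        res = run_evaluation(rows, windows, cfg)
        names = list(res.importance)
        k = res.retained_ranks[0]
        assert names[:k] == [f"pc{i}" for i in range(1, k + 1)]
        assert names[k:] == ["alpha1", "alpha2", "mean_nn", "bp1", "bp2", "bp3",
                             "bp4", "bp5", "hjorth_complexity", "hjorth_mobility"]

    def test_pca_refit_ignores_test_windows(self, small_problem):
        # mutate the windows of records that land in the test split; the
        # trained PCA (and hence the train-row coefficients) must not move
        rows, windows = small_problem
        cfg = EvalConfig(n_trials=1, seed=3, classifiers=("random_forest",),
                         n_trees=50, compute_importance=False)
        balanced = balance_by_undersampling(rows.reset_index(drop=True), None)
        from vtwarn.classify import split_train_test as _split  # same derived seeds
        sub = np.random.SeedSequence(3).spawn(5)
        seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in sub]
        balanced = balance_by_undersampling(rows.reset_index(drop=True), seeds[0])
        train, test = _split(balanced, 0.8, seeds[1])
        from vtwarn.pca import fit_windows

        before = fit_windows(windows[train.index.to_numpy()])
        w2 = windows.copy()
        w2[test.index.to_numpy()] += 0.3
        after = fit_windows(w2[train.index.to_numpy()])
        np.testing.assert_array_equal(before.left_vectors, after.left_vectors)
        assert before.k == after.k
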