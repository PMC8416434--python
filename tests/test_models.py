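import hashlib

import numpy as np
import pandas as pd
import pytest

from qeeg import (
    FeatureCombination,
    FeatureMatrix,
    GridSearchSVM,
    ModelSpec,
    TunedRandomForest,
    build_feature_matrix,
    cross_validate,
    evaluate_fold,
    stratified_kfold,
)
from qeeg.errors import (
    FitFailureError,
    InfeasibleStratificationError,
    MetricUndefinedError,
)
from qeeg.models import mann_whitney_auc


class TestStratifiedKFold:
    def test_balanced_cohort_gives_five_and_five_per_fold(self):
        y = np.repeat([1, 0], 50)
        assign = stratified_kfold(y, k=10, seed=0)
        for fold in range(1, 11):
            mask = assign == fold
            assert mask.sum() == 10
            assert y[mask].sum() == 5

    def test_deterministic_given_seed(self):
        y = np.repeat([1, 0], 50)
        a = stratified_kfold(y, 10, seed=3)
        b = stratified_kfold(y, 10, seed=3)
        c = stratified_kfold(y, 10, seed=4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_small_class_is_infeasible(self):
        y = np.r_[np.ones(9), np.zeros(91)]
        with pytest.raises(InfeasibleStratificationError):
            stratified_kfold(y, k=10, seed=0)

    def test_every_subject_in_exactly_one_fold(self):
        y = np.repeat([1, 0], [37, 44])
        assign = stratified_kfold(y, 10, seed=1)
        assert assign.min() >= 1 and assign.max() == 10
        sizes = np.bincount(assign)[1:]
        assert sizes.max() - sizes.min() <= 1


class TestFoldMetrics:
    def test_worked_example_auc(self):
        auc, _, _ = evaluate_fold(
            scores=[0.9, 0.4, 0.6, 0.2], probs=[0.9, 0.4, 0.6, 0.2], labels=[1, 1, 0, 0]
        )
        assert auc == 0.75  # 3 of 4 case-control pairs concordant

    def test_perfect_ranking_and_calibration(self):
        auc, sens, spec = evaluate_fold([3.0, 2.0, -1.0], [0.9, 0.8, 0.1], [1, 1, 0])
        assert (auc, sens, spec) == (1.0, 1.0, 1.0)

    def test_all_tied_scores_give_half(self):
        auc, _, _ = evaluate_fold([1.0] * 6, [0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert auc == 0.5

    def test_single_class_fold_is_undefined(self):
        with pytest.raises(MetricUndefinedError):
            evaluate_fold([0.1, 0.2], [0.1, 0.2], [1, 1])

    def test_auc_equals_brute_force_pair_counting_on_random_instances(self):
        """Mann-Whitney AUC vs exhaustive concordant/tied pair counting."""
        rng = np.random.default_rng(0)
        for _ in range(500):
            n = rng.integers(4, 12)
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, rng.integers(1, n), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            pairs = wins = 0
            for i in np.flatnonzero(labels == 1):
                for j in np.flatnonzero(labels == 0):
                    pairs += 1
                    wins += (scores[i] > scores[j]) + 0.5 * (scores[i] == scores[j])
            assert mann_whitney_auc(labels, scores) == pytest.approx(wins / pairs)


class TestSVM:
    def test_separable_toy_data_is_fit_perfectly(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 20)
        X = rng.standard_normal((40, 2)) + 6.0 * y[:, None]
        est = GridSearchSVM(inner_cv=3).fit(X, y)
        assert est.C_ in (0.1, 0.5, 1, 5, 10)
        assert np.all(est.predict(X) == y)

    def test_shuffled_labels_give_chance_level_inner_auc(self):
        hits = 0
        n_rep = 40
        for k in range(n_rep):
            rng = np.random.default_rng(3000 + k)
            y = rng.permutation(np.repeat([0, 1], 40))
            X = rng.standard_normal((80, 5))
            # single fixed C isolates the null inner-CV AUC from the
            # upward bias of maximising over the grid
            est = GridSearchSVM(c_grid=(1.0,), inner_cv=3, random_state=k).fit(X, y)
            if 0.3 <= est.cv_auc_[0] <= 0.7:
                hits += 1
        assert hits >= int(0.9 * n_rep)

    def test_degenerate_single_class_fold_fails(self):
        X = np.random.default_rng(2).standard_normal((10, 3))
        with pytest.raises(FitFailureError):
            GridSearchSVM().fit(X, np.ones(10))


class TestRandomForest:
    def test_mtry_is_floor_sqrt_p(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 15)
        X = rng.standard_normal((30, 190))
        est = TunedRandomForest(n_trees=10).fit(X, y)
        assert est.mtry_ == 13  # floor(sqrt(190))

    def test_pure_signal_feature_tops_importance(self):
        hits = 0
        n_rep = 25
        for k in range(n_rep):
            rng = np.random.default_rng(4000 + k)
            y = np.repeat([0, 1], 25)
            X = rng.standard_normal((50, 8))
            X[:, 3] += 3.0 * y
            est = TunedRandomForest(n_trees=100, random_state=k).fit(X, y)
            if np.argmax(est.feature_importances_) == 3:
                hits += 1
        assert hits >= int(0.95 * n_rep)

    def test_probabilities_are_tree_vote_fractions(self):
        rng = np.random.default_rng(4)
        y = np.repeat([0, 1], 15)
        X = rng.standard_normal((30, 4))
        est = TunedRandomForest(n_trees=50, random_state=0).fit(X, y)
        proba = est.predict_proba(X)
        assert proba.shape == (30, 2)
        assert np.all((proba >= 0) & (proba <= 1))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)


def _toy_feature_matrix(seed=0, n_per=30, p=6, effect=0.0):
    rng = np.random.default_rng(seed)
    y = np.repeat([1, 0], n_per)
    X = rng.standard_normal((2 * n_per, p))
    X[:, 0] += effect * y
    df = pd.DataFrame(X, columns=[f"f{j}" for j in range(p)],
                      index=[f"s{i}" for i in range(2 * n_per)])
    return FeatureMatrix(df, y)


class TestCrossValidate:
    def test_deterministic_end_to_end(self, desk_spec):
        fm = _toy_feature_matrix(seed=5, effect=1.0)
        a = cross_validate(fm, desk_spec)
        b = cross_validate(fm, desk_spec)
        assert a.fold_assignments.equals(b.fold_assignments)
        pd.testing.assert_frame_equal(a.fold_metrics, b.fold_metrics)
        pd.testing.assert_frame_equal(a.coefficients, b.coefficients)

    def test_summary_recomputable_from_fold_values(self, desk_spec):
        fm = _toy_feature_matrix(seed=6, effect=1.0)
        cv = cross_validate(fm, desk_spec)
        s = cv.summary()
        vals = cv.fold_metrics["auc"].to_numpy() * 100
        assert s["auc_mean"] == pytest.approx(vals.mean())
        assert s["auc_sd"] == pytest.approx(vals.std(ddof=1))
        assert len(cv.fold_metrics) == 10

    def test_en_coefficients_kept_per_fold(self, desk_spec):
        fm = _toy_feature_matrix(seed=7, effect=2.0)
        cv = cross_validate(fm, desk_spec)
        assert cv.coefficients.shape == (10, 6)
        assert (cv.coefficients["f0"] != 0).sum() >= 8  # strong feature persists

    def test_no_leakage_from_test_fold_rows(self, desk_spec):
        """Permuting a feature within the held-out rows never changes the
        training fit: fold hashes must be identical."""

        def fold1_coef_hash(fm):
            cv = cross_validate(fm, desk_spec)
            return hashlib.sha256(
                np.ascontiguousarray(cv.coefficients.to_numpy())
            ).hexdigest(), cv.fold_assignments

        fm = _toy_feature_matrix(seed=8, effect=1.0)
        h1, assign = fold1_coef_hash(fm)
        X2 = fm.X.copy()
        test_rows = assign[assign == 1].index
        rng = np.random.default_rng(0)
        X2.loc[test_rows, "f3"] = rng.permutation(X2.loc[test_rows, "f3"].to_numpy())
        # fold 1's own test metrics change, but training fits (coefs of
        # fold 1 use the other 9/10) -- only folds whose TRAIN set contains
        # the permuted rows may differ; fold 1's coefficients must not.
        cv2 = cross_validate(FeatureMatrix(X2, fm.y), desk_spec)
        cv1 = cross_validate(fm, desk_spec)
        pd.testing.assert_series_equal(
            cv1.coefficients.loc[1], cv2.coefficients.loc[1]
        )

    def test_methods_share_fold_assignments(self, desk_spec):
        from dataclasses import replace

        fm = _toy_feature_matrix(seed=9, effect=1.5)
        cv_en = cross_validate(fm, desk_spec)
        cv_rf = cross_validate(fm, replace(desk_spec, method="RF", rf_n_trees=20))
        assert cv_en.fold_assignments.equals(cv_rf.fold_assignments)
        assert cv_rf.coefficients is None


class TestModelSpec:
    def test_defaults_match_the_protocol(self):
        spec = ModelSpec()
        assert spec.svm_c_grid == (0.1, 0.5, 1, 5, 10)
        assert spec.outer_folds == 10
        assert spec.en_mixing == 0.5

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(method="XGB")

    def test_invalid_mixing_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(en_mixing=0.0)


class TestPenaltyFreeCovariates:
    def test_exempt_covariate_stays_in_the_null_model(self):
        """With the covariate penalty lifted, covariates behave like a
        plain logistic adjustment even at the heaviest penalty."""
        import statsmodels.api as sm

        from qeeg._cd import en_logistic_path, lambda_path

        rng = np.random.default_rng(11)
        y = np.repeat([0.0, 1.0], 40)
        X = rng.standard_normal((80, 6))
        X[:, 5] += 0.8 * y  # informative "covariate"
        X = (X - X.mean(0)) / X.std(0)
        pf = np.ones(6)
        pf[5] = 0.0
        lams = lambda_path(X, y, 0.5, 6, penalty_factor=pf)
        coefs, _, _ = en_logistic_path(X, y, lams, 0.5, 1e-8, penalty_factor=pf)
        assert np.all(coefs[0][:5] == 0.0)
        ref = sm.Logit(y, sm.add_constant(X[:, 5])).fit(disp=0)
        assert coefs[0][5] == pytest.approx(ref.params[1], abs=1e-4)

    def test_spec_flag_exempts_cov_columns(self, desk_spec):
        from dataclasses import replace

        fm = _toy_feature_matrix(seed=12, effect=0.0)
        fm.X.columns = [*fm.X.columns[:-1], "cov_age"]
        spec = replace(desk_spec, en_penalize_covariates=False,
                       en_n_lambdas=3, en_lambda_min_ratio=0.98)
        cv = cross_validate(fm, spec)
        # near lambda_max every penalized feature is dropped in every
        # fold, but the exempt covariate never is
        assert (cv.coefficients["cov_age"] != 0).all()
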