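"""Tests of fold construction, scoring and the cross-validation engine."""

import numpy as np
import pytest
from sklearn.metrics import r2_score

import confaudit.cv as cv_module
from confaudit import (
    DataError,
    FoldError,
    PipelineConfig,
    RemovalModelSpec,
    StratifiedRegressionKFold,
    UndefinedScoreError,
    pure_noise_scenario,
    r_squared,
    run_cv,
    stratified_folds,
)
from confaudit.cv import _plain_folds


class TestStratifiedFolds:
    def test_each_fold_gets_one_member_per_decile(self):
        y = np.arange(1, 101, dtype=float)
        labels = stratified_folds(y, k=10, n_bins=10, seed=0)
        for b in range(10):
            decile_labels = labels[b * 10 : (b + 1) * 10]
            assert sorted(decile_labels) == list(range(10))

    def test_fold_sizes_balanced(self):
        labels = stratified_folds(np.random.default_rng(0).normal(size=20), 10, 2, 1)
        assert all(np.sum(labels == f) == 2 for f in range(10))

    def test_sizes_differ_by_at_most_one(self):
        y = np.random.default_rng(5).normal(size=103)
        labels = stratified_folds(y, 10, 10, 2)
        sizes = np.bincount(labels, minlength=10)
        assert sizes.max() - sizes.min() <= 1

    def test_constant_target_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="constant target"):
            labels = stratified_folds(np.ones(30), 5, 10, 0)
        assert np.bincount(labels).tolist() == [6] * 5

    def test_few_distinct_values_rank_binning_fallback(self):
        y = np.repeat([1.0, 2.0, 3.0], 20)
        with pytest.warns(UserWarning, match="rank-based"):
            labels = stratified_folds(y, 5, 10, 0)
        sizes = np.bincount(labels, minlength=5)
        assert sizes.max() - sizes.min() <= 1

    def test_splitter_protocol(self):
        y = np.random.default_rng(1).normal(size=40)
        splitter = StratifiedRegressionKFold(n_splits=4, n_bins=5, seed=2)
        assert splitter.get_n_splits() == 4
        seen = []
        for train, test in splitter.split(None, y):
            assert len(np.intersect1d(train, test)) == 0
            seen.extend(test.tolist())
        assert sorted(seen) == list(range(40))

    def test_stratification_balances_fold_means_on_average(self):
        """Quantile stratification yields more homogeneous per-fold target
        means than a plain shuffled partition, across seeds."""
        wins = 0
        for seed in range(50):
            y = np.exp(np.random.default_rng(seed).normal(size=150))
            strat = stratified_folds(y, 5, 10, seed)
            plain = _plain_folds(150, 5, seed)
            v_s = np.var([y[strat == f].mean() for f in range(5)])
            v_p = np.var([y[plain == f].mean() for f in range(5)])
            wins += v_s < v_p
        assert wins >= 40


class TestRSquared:
    @pytest.mark.parametrize(
        "y_true, y_pred, expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [2, 2, 2], 0.0),
            ([0, 2], [2, 0], -3.0),  # SS_res = 8, SS_tot = 2
        ],
    )
    def test_examples(self, y_true, y_pred, expected):
        assert r_squared(y_true, y_pred) == expected

    def test_matches_sklearn_on_random_data(self):
        rng = np.random.default_rng(6)
        y, pred = rng.normal(size=100), rng.normal(size=100)
        assert r_squared(y, pred) == pytest.approx(r2_score(y, pred), abs=1e-12)

    def test_constant_truth_is_undefined(self):
        with pytest.raises(UndefinedScoreError):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            r_squared([1, 2, 3], [1, 2])


@pytest.fixture
def small_problem():
    rng = np.random.default_rng(8)
    n = 100
    X = rng.normal(size=(n, 6))
    C = rng.normal(size=(n, 2))
    y = 0.8 * X[:, 0] + rng.normal(size=n)
    return X, C, y


_FAST = {"n_estimators": 15}


class TestRunCV:
    def test_partition_property(self, small_problem):
        X, C, y = small_problem
        cfg = PipelineConfig(k_folds=5, seed=1, predictor=_FAST)
        res = run_cv(X, C, y, cfg)
        assert len(res.fold_scores) == 5
        sizes = np.bincount(res.fold_assignments, minlength=5)
        assert sizes.sum() == len(y) and sizes.max() - sizes.min() <= 1
        assert res.mean_score == pytest.approx(res.fold_scores.mean(), abs=1e-12)

    def test_oracle_feature_dominates(self):
        rng = np.random.default_rng(9)
        n = 200
        y = rng.normal(size=n)
        X = np.column_stack([y, rng.normal(size=(n, 9))])
        cfg = PipelineConfig(
            k_folds=10, seed=0, removal=RemovalModelSpec("none"), predictor={"n_estimators": 50}
        )
        assert run_cv(X, rng.normal(size=(n, 2)), y, cfg).mean_score > 0.9

    def test_pure_noise_scores_at_or_below_chance(self):
        for seed in range(10):
            ds = pure_noise_scenario(seed)
            cfg = PipelineConfig(
                k_folds=5,
                seed=seed,
                removal=RemovalModelSpec("none"),
                predictor={"n_estimators": 25},
                compute_importances=False,
            )
            assert run_cv(ds.X, ds.C, ds.y, cfg).mean_score <= 0.05

    def test_determinism(self, small_problem):
        X, C, y = small_problem
        cfg = PipelineConfig(k_folds=4, seed=3, predictor=_FAST)
        a, b = run_cv(X, C, y, cfg), run_cv(X, C, y, cfg)
        np.testing.assert_array_equal(a.fold_scores, b.fold_scores)
        np.testing.assert_array_equal(a.fold_assignments, b.fold_assignments)
        np.testing.assert_array_equal(a.fold_importances, b.fold_importances)

    def test_remover_fitted_on_training_rows_only(self, small_problem, monkeypatch):
        """Spy on remover fitting: it must see exactly the training rows of
        each fold, never the full data."""
        X, C, y = small_problem
        calls = []
        original = cv_module.fit_remover

        def spy(X_train, C_train, spec):
            calls.append(X_train.shape[0])
            return original(X_train, C_train, spec)

        monkeypatch.setattr(cv_module, "fit_remover", spy)
        cfg = PipelineConfig(k_folds=5, seed=2, predictor=_FAST)
        run_cv(X, C, y, cfg)
        assert len(calls) == 5
        assert all(c == 80 for c in calls)  # 4/5 of 100 rows

    def test_none_family_skips_remover(self, small_problem, monkeypatch):
        X, C, y = small_problem

        def boom(*args, **kwargs):  # pragma: no cover
            raise AssertionError("remover must not be fitted for family 'none'")

        monkeypatch.setattr(cv_module, "fit_remover", boom)
        cfg = PipelineConfig(
            k_folds=4, seed=2, removal=RemovalModelSpec("none"), predictor=_FAST
        )
        run_cv(X, C, y, cfg)

    def test_zero_variance_feature_warns_and_completes(self, small_problem):
        X, C, y = small_problem
        X = X.copy()
        X[:, 0] = 5.0
        cfg = PipelineConfig(k_folds=4, seed=1, predictor=_FAST)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = run_cv(X, C, y, cfg)
        assert np.all(np.isfinite(res.fold_scores))

    def test_failures_carry_fold_index(self, small_problem):
        X, C, _ = small_problem
        with pytest.warns(UserWarning):
            with pytest.raises(FoldError) as err:
                run_cv(X, C, np.ones(len(X)), PipelineConfig(k_folds=4, predictor=_FAST))
        assert err.value.fold == 0

    def test_scaling_scope_is_inert_for_tree_predictors(self, small_problem):
        """Fold-wise and global z-scoring give identical scores: both are
        per-feature affine maps, linear residualization commutes with them,
        and tree splits are invariant under them.  The sensitivity flag
        exists to demonstrate exactly this."""
        X, C, y = small_problem
        a = run_cv(X, C, y, PipelineConfig(k_folds=4, seed=1, predictor=_FAST))
        b = run_cv(
            X, C, y, PipelineConfig(k_folds=4, seed=1, predictor=_FAST, global_scaling=True)
        )
        np.testing.assert_allclose(a.fold_scores, b.fold_scores, atol=1e-12)

    def test_final_estimator_importance(self, small_problem):
        """The full-data refit yields a normalized importance vector that
        concentrates on the genuinely informative feature."""
        from confaudit import fit_final_estimator

        X, C, y = small_problem
        cfg = PipelineConfig(k_folds=4, seed=1, predictor={"n_estimators": 30})
        forest, imp = fit_final_estimator(X, C, y, cfg)
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)
        assert imp.argmax() == 0  # y was built from X[:, 0]
        _, imp2 = fit_final_estimator(X, C, y, cfg)
        np.testing.assert_array_equal(imp, imp2)

    def test_k_exceeding_n_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(Exception):
            run_cv(
                rng.normal(size=(5, 2)),
                rng.normal(size=(5, 1)),
                rng.normal(size=5),
                PipelineConfig(k_folds=10, predictor=_FAST),
            )
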