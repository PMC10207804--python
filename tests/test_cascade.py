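import numpy as np
import pytest
from sklearn.linear_model import Lasso

from radcascade.cascade import (
    RobustScaler,
    cv_lasso,
    fit_cascade,
    lasso_coordinate_descent,
    make_lambda_grid,
    predict_cascade,
    stratified_folds,
    youden_threshold,
)
from conftest import make_label_table


class TestRobustScaler:
    def test_outlier_excluded_in_second_pass(self, rng):
        base = rng.normal(0.0, 1.0, size=40)
        vals = np.concatenate([base, [50.0]])  # |z| of 50 is far above 3
        sc = RobustScaler().fit(vals)
        assert abs(sc.center[0] - base.mean()) < 0.2
        assert abs(sc.scale[0] - base.std(ddof=1)) < 0.2
        # without exclusion the outlier would inflate the SD several-fold
        assert sc.scale[0] < np.std(vals, ddof=1) / 3

    def test_standardized_sample_is_near_identity(self, rng):
        x = rng.normal(size=500)
        x = (x - x.mean()) / x.std(ddof=1)
        sc = RobustScaler().fit(x)
        assert sc.center[0] == pytest.approx(0.0, abs=0.05)
        assert sc.scale[0] == pytest.approx(1.0, abs=0.05)

    def test_zero_variance_maps_to_zero(self):
        sc = RobustScaler().fit(np.full(10, 4.2))
        out = sc.transform(np.array([4.2, 100.0, -5.0]))
        np.testing.assert_array_equal(out, 0.0)

    def test_validation_transform_uses_training_parameters_only(self, rng):
        train = rng.normal(5, 2, size=60)
        sc = RobustScaler().fit(train)
        v1 = sc.transform(np.array([1.0]))
        # "changing validation data" cannot alter the transform of other points
        sc2 = RobustScaler().fit(train)
        v2 = sc2.transform(np.array([1.0, 999.0]))[0]
        assert v1[0] == v2


class TestLasso:
    def test_zero_penalty_recovers_ols(self, rng):
        X = rng.normal(size=(50, 6))
        y = X @ rng.normal(size=6) + rng.normal(0, 0.1, size=50) + 2.0
        beta, b0 = lasso_coordinate_descent(X, y, lam=0.0)
        A = np.column_stack([np.ones(50), X])
        ols = np.linalg.lstsq(A, y, rcond=None)[0]
        assert b0 == pytest.approx(ols[0], abs=1e-6)
        np.testing.assert_allclose(beta, ols[1:], atol=1e-6)

    def test_orthonormal_design_soft_threshold_closed_form(self, rng):
        n, p = 64, 8
        M = rng.normal(size=(n, p))
        M -= M.mean(axis=0)
        Q, _ = np.linalg.qr(M)
        X = Q * np.sqrt(n)  # X^T X / n = I, columns centered
        y = rng.normal(size=n)
        yc = y - y.mean()
        b_ols = X.T @ yc / n
        for lam in (0.01, 0.05, 0.2):
            beta, _ = lasso_coordinate_descent(X, y, lam=lam)
            expected = np.sign(b_ols) * np.maximum(np.abs(b_ols) - lam, 0.0)
            np.testing.assert_allclose(beta, expected, atol=1e-8)

    def test_lambda_max_gives_exact_zeros(self, rng):
        X = rng.normal(size=(40, 10))
        y = rng.integers(0, 2, size=40).astype(float)
        lam_max = make_lambda_grid(X, y)[0]
        for lam in (lam_max, lam_max * 1.5):
            beta, b0 = lasso_coordinate_descent(X, y, lam=lam)
            assert np.all(beta == 0.0)
            assert b0 == pytest.approx(y.mean())

    def test_agrees_with_sklearn(self, rng):
        X = rng.normal(size=(45, 7))
        y = X[:, 0] - 0.5 * X[:, 3] + rng.normal(0, 0.5, size=45)
        for lam in (0.02, 0.1, 0.5):
            beta, b0 = lasso_coordinate_descent(X, y, lam=lam)
            sk = Lasso(alpha=lam, fit_intercept=True, tol=1e-10, max_iter=100000).fit(X, y)
            np.testing.assert_allclose(beta, sk.coef_, atol=1e-5)
            assert b0 == pytest.approx(sk.intercept_, abs=1e-5)

    def test_l1_norm_monotone_on_orthonormal_design(self, rng):
        n, p = 64, 6
        Q, _ = np.linalg.qr(rng.normal(size=(n, p)) - 0.0)
        X = Q * np.sqrt(n)
        y = rng.normal(size=n)
        norms = []
        for lam in np.geomspace(1e-3, 1.0, 12):
            beta, _ = lasso_coordinate_descent(X, y, lam=lam)
            norms.append(np.abs(beta).sum())
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


class TestCvLasso:
    def _data(self, rng, n=60):
        X = rng.normal(size=(n, 8))
        y = (X[:, 0] + rng.normal(0, 0.8, size=n) > 0).astype(float)
        return X, y

    def test_selected_lambda_attains_minimum(self, rng):
        X, y = self._data(rng)
        coef, b0, grid, cv_mse = cv_lasso(X, y, seed=1)
        assert cv_mse.argmin() == np.flatnonzero(grid == grid[cv_mse.argmin()])[0]
        beta_max, _ = lasso_coordinate_descent(X, y, lam=grid[0])
        assert np.all(beta_max == 0.0)  # largest grid lambda nulls everything

    def test_row_shuffle_with_same_folds_is_invariant(self, rng):
        X, y = self._data(rng)
        folds = stratified_folds(y, 5, seed=3)
        _, _, grid1, mse1 = cv_lasso(X, y, folds=folds)
        perm = rng.permutation(len(y))
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        folds_p = [np.sort(inv[f]) for f in folds]  # same subjects per fold
        _, _, grid2, mse2 = cv_lasso(X[perm], y[perm], folds=folds_p)
        np.testing.assert_allclose(grid1, grid2)
        np.testing.assert_allclose(mse1, mse2, atol=1e-10)
        assert grid1[mse1.argmin()] == pytest.approx(grid2[mse2.argmin()])

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(ValueError, match="single class"):
            cv_lasso(X, np.ones(20))

    def test_small_minority_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.zeros(20)
        y[:3] = 1
        with pytest.raises(ValueError, match="minority"):
            cv_lasso(X, y, n_folds=5)


class TestCascade:
    def test_clinical_feature_set_is_age_gender(self, rng):
        table = make_label_table(rng, n_per_class=(10, 12, 20), class_shift=1.0)
        model = fit_cascade(table, feature_set="clinical", seed=0)
        assert model.stage1.feature_names == ["age", "gender"]
        assert model.stage2.feature_names == ["age", "gender"]

    def test_stage2_uses_only_gnb_nb_training_rows(self, rng):
        from radcascade.cascade import _fit_stage

        table = make_label_table(rng, n_per_class=(10, 12, 20), class_shift=1.0)
        model = fit_cascade(
            table, "clinical_radiomic", ranked_features=["feat_000", "feat_001", "age"],
            seed=7,
        )
        sub = table[table["label"].isin(["GNB", "NB"])]
        y2 = (sub["label"] == "GNB").to_numpy(dtype=float)
        ref = _fit_stage(
            sub, ["feat_000", "feat_001", "age"], y2, "GNB", 8, 5, 100, 1e-4, "youden"
        )
        np.testing.assert_array_equal(model.stage2.coefficients, ref.coefficients)
        np.testing.assert_array_equal(model.stage2.scaler.center, ref.scaler.center)

    def test_refit_is_bit_identical(self, rng):
        table = make_label_table(rng, n_per_class=(10, 12, 20), class_shift=1.0)
        kw = dict(feature_set="clinical_radiomic",
                  ranked_features=["feat_000", "feat_001", "feat_002", "age"], seed=3)
        m1 = fit_cascade(table, **kw)
        m2 = fit_cascade(table, **kw)
        np.testing.assert_array_equal(m1.stage1.coefficients, m2.stage1.coefficients)
        np.testing.assert_array_equal(m1.stage2.coefficients, m2.stage2.coefficients)
        assert m1.stage1.threshold == m2.stage1.threshold

    def test_predict_short_circuits_stage2(self, rng):
        table = make_label_table(rng, n_per_class=(10, 12, 20), class_shift=2.0)
        model = fit_cascade(
            table, "clinical_radiomic",
            ranked_features=["feat_000", "feat_001", "age"], seed=1,
        )
        preds = predict_cascade(model, table)
        gn_pred = preds["predicted"] == "GN"
        assert gn_pred.any()
        assert preds.loc[gn_pred, "stage2_score"].isna().all()
        assert preds.loc[~gn_pred, "stage2_score"].notna().all()
        # partition: one class per subject
        assert preds["predicted"].isin(["GN", "GNB", "NB"]).all()
        assert len(preds) == len(table)

    def test_all_zero_coefficients_single_predicted_class(self, rng):
        table = make_label_table(rng, n_per_class=(10, 12, 20))
        model = fit_cascade(
            table, "clinical_radiomic", ranked_features=["feat_000", "age"], seed=2,
        )
        model.stage1.coefficients[:] = 0.0
        model.stage2.coefficients[:] = 0.0
        model.stage1.threshold = model.stage1.intercept + 1.0  # intercept below cut
        model.stage2.threshold = model.stage2.intercept - 1.0
        preds = predict_cascade(model, table)
        assert set(preds["predicted"]) == {"GNB"}

    def test_missing_feature_raises_schema_error(self, rng):
        table = make_label_table(rng, n_per_class=(10, 12, 20))
        model = fit_cascade(
            table, "clinical_radiomic", ranked_features=["feat_000", "age"], seed=2,
        )
        with pytest.raises(KeyError, match="feat_000"):
            predict_cascade(model, table.drop(columns=["feat_000"]))


def test_youden_threshold_maximizes_j():
    scores = np.array([0.1, 0.2, 0.4, 0.6, 0.8, 0.9])
    y = np.array([0, 0, 0, 1, 1, 1])
    t = youden_threshold(scores, y)
    assert t == pytest.approx(0.6)  # perfect separation at the smallest positive
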