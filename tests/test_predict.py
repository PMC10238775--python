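"""Prediction-stack contracts: filters, PCA, ridge closed form, leakage-free CV."""

import numpy as np
import pandas as pd
import pytest

from countylang.predict import (
    PipelineConfig,
    compare_models,
    cross_validate,
    evaluate,
    fit_ridge,
    fit_transform_pca,
    remove_low_variance,
)


def _sample_var(col):
    # independent hand formula: sum((x - mean)^2) / (n - 1)
    m = sum(col) / len(col)
    return sum((x - m) ** 2 for x in col) / (len(col) - 1)


class TestLowVariance:
    def test_crafted_variances_kept_exactly(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(6)
        base -= base.mean()
        base /= np.sqrt(_sample_var(base))          # unit sample variance
        cols = [
            np.zeros(6),                            # var 0
            base * np.sqrt(1e-9),                   # var 1e-9
            base * np.sqrt(0.1),                    # var 0.1
            base,                                   # var 1
            base * np.sqrt(2.0),                    # var 2
        ]
        X = np.column_stack(cols)
        for j, expected in enumerate([0.0, 1e-9, 0.1, 1.0, 2.0]):
            assert _sample_var(X[:, j]) == pytest.approx(expected, rel=1e-9, abs=1e-15)
        _, kept = remove_low_variance(X, floor=1e-8)
        assert list(kept) == [2, 3, 4]

    def test_constant_column_dropped_at_any_floor(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        _, kept = remove_low_variance(X, floor=0.0)
        assert list(kept) == [1]

    def test_zero_floor_is_identity_without_constants(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10, 4))
        reduced, kept = remove_low_variance(X, floor=0.0)
        assert reduced.shape == X.shape and list(kept) == [0, 1, 2, 3]

    def test_all_dropped_raises(self):
        with pytest.raises(ValueError):
            remove_low_variance(np.ones((5, 3)), floor=0.0)


class TestPCA:
    def test_collinear_data_needs_one_component(self):
        t = np.linspace(-1, 1, 20)
        X = np.column_stack([t, 3 * t + 2])
        pca, scores = fit_transform_pca(X, variance_retained=0.99)
        assert pca.n_components_ == 1
        recon = pca.pca_.inverse_transform(scores)
        np.testing.assert_allclose(recon, X, atol=1e-9)

    def test_explained_variance_matches_eigendecomposition(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 5)) @ rng.standard_normal((5, 5))
        pca, _ = fit_transform_pca(X, variance_retained=1.0)
        cov = np.cov(X, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(pca.explained_variance_, eig[:5], atol=1e-9)

    def test_full_retention_caps_at_rank(self):
        rng = np.random.default_rng(4)
        pca, _ = fit_transform_pca(rng.standard_normal((6, 10)), variance_retained=1.0)
        assert pca.n_components_ == 5  # min(rows-1, cols)

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            fit_transform_pca(np.ones((5, 2)), 0.95)


def _ridge_closed_form(X, y, lam):
    # oracle: (Xc'Xc + lam I)^-1 Xc' yc on centered data
    xm, ym = X.mean(axis=0), y.mean()
    Xc, yc = X - xm, y - ym
    beta = np.linalg.solve(Xc.T @ Xc + lam * np.eye(X.shape[1]), Xc.T @ yc)
    return beta, ym - xm @ beta


class TestRidge:
    @pytest.mark.parametrize("lam", [0.0, 1.0, 100.0])
    def test_matches_closed_form(self, lam):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((10, 3))
        y = rng.standard_normal(10)
        coef, intercept = fit_ridge(X, y, lam)
        beta, b0 = _ridge_closed_form(X, y, lam)
        np.testing.assert_allclose(coef, beta, atol=1e-10)
        assert intercept == pytest.approx(b0, abs=1e-10)

    def test_zero_penalty_equals_ols(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((30, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + rng.standard_normal(30)
        coef, intercept = fit_ridge(X, y, 0.0)
        ols = np.linalg.lstsq(np.column_stack([np.ones(30), X]), y, rcond=None)[0]
        np.testing.assert_allclose(coef, ols[1:], atol=1e-10)
        assert intercept == pytest.approx(ols[0], abs=1e-10)

    def test_infinite_shrinkage_predicts_mean(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        coef, intercept = fit_ridge(X, y, 1e12)
        np.testing.assert_allclose(coef, 0.0, atol=1e-9)
        assert intercept == pytest.approx(y.mean(), abs=1e-9)

    def test_ridge_path_is_continuous_in_lambda(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((25, 4))
        y = rng.standard_normal(25)
        c1, _ = fit_ridge(X, y, 10.0)
        c2, _ = fit_ridge(X, y, 10.0 + 1e-6)
        assert np.max(np.abs(c1 - c2)) < 1e-6

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            fit_ridge(np.array([[np.nan]]), np.array([1.0]), 1.0)


def _features(n, p, seed):
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"{i:05d}" for i in range(n)], name="county_id")
    return pd.DataFrame(rng.standard_normal((n, p)), index=idx)


class TestCrossValidate:
    def test_noiseless_linear_signal_recovered(self):
        X = _features(200, 2, 0)
        y = 3.0 * X[0] - 2.0 * X[1] + 10.0
        cv = cross_validate(X, y, PipelineConfig(seed=0))
        assert cv.pooled_r >= 0.999

    def test_permuted_labels_have_no_signal(self):
        # Under the null, pooled CV correlation is not centered exactly at 0:
        # shrunk predictions track the training-fold mean, which is
        # anti-correlated with the held-out fold mean, a known ~-1/(k-1)
        # bias.  Assert no positive signal and magnitude within that bias.
        rs = []
        for seed in range(20):
            X = _features(500, 5, seed)
            rng = np.random.default_rng(100 + seed)
            y = pd.Series(rng.standard_normal(500), index=X.index)
            rs.append(cross_validate(X, y, PipelineConfig(seed=seed)).pooled_r)
        assert -0.15 < np.mean(rs) < 0.1

    def test_folds_partition_counties(self):
        X = _features(103, 3, 1)
        y = X[0] + pd.Series(np.random.default_rng(0).standard_normal(103), index=X.index)
        cv = cross_validate(X, y, PipelineConfig(seed=2))
        sizes = cv.fold_assignment.value_counts()
        assert len(sizes) == 10 and sizes.max() - sizes.min() <= 1
        assert set(cv.oos_predictions.index) == set(X.index)
        assert not cv.oos_predictions.isna().any()

    def test_held_out_label_cannot_influence_own_prediction(self):
        # mutating one county's outcome must not move its own held-out
        # prediction (it only enters other folds' training sets)
        X = _features(60, 4, 3)
        rng = np.random.default_rng(3)
        y = X[0] + pd.Series(rng.standard_normal(60), index=X.index)
        cfg = PipelineConfig(seed=5, k_folds=5)
        cv1 = cross_validate(X, y, cfg)
        target = X.index[17]
        y2 = y.copy()
        y2.loc[target] += 1000.0
        cv2 = cross_validate(X, y2, cfg)
        assert cv2.oos_predictions.loc[target] == cv1.oos_predictions.loc[target]
        assert cv1.fold_assignment.equals(cv2.fold_assignment)

    def test_small_folds_raise(self):
        X = _features(15, 2, 4)
        y = X[0]
        with pytest.raises(ValueError):
            cross_validate(X, y, PipelineConfig(seed=0, k_folds=10))

    def test_accuracy_degrades_with_outcome_noise(self):
        grid = [0.5, 1.0, 2.0, 4.0]
        means = []
        for sd in grid:
            rs = []
            for seed in range(10):
                X = _features(200, 10, seed)
                rng = np.random.default_rng(1000 + seed)
                beta = np.ones(10)
                y = pd.Series(
                    X.to_numpy() @ beta + sd * rng.standard_normal(200), index=X.index
                )
                rs.append(cross_validate(X, y, PipelineConfig(seed=seed)).pooled_r)
            means.append(np.mean(rs))
        for lo, hi in zip(means[1:], means[:-1]):
            assert lo <= hi + 0.05


class TestEvaluate:
    def test_perfect_and_inverted_predictions(self):
        y = np.array([1.0, 2.0, 5.0, 3.0, 4.0])
        m = evaluate(y, y)
        assert m["pearson_r"] == pytest.approx(1.0) and m["mae"] == 0.0
        inv = evaluate(-(y - y.mean()), y)
        assert inv["pearson_r"] == pytest.approx(-1.0)

    def test_five_point_fixture_matches_hand_formula(self):
        pred = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        y = np.array([1.0, 2.0, 3.0, 5.0, 4.0])
        # hand Pearson: sum products of centered values over root sums
        pc, yc = pred - pred.mean(), y - y.mean()
        expected = float((pc * yc).sum() / np.sqrt((pc**2).sum() * (yc**2).sum()))
        assert evaluate(pred, y)["pearson_r"] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_prediction_flagged_not_raised(self):
        m = evaluate(np.ones(5), np.arange(5.0))
        assert m["degenerate"] and np.isnan(m["pearson_r"])


class TestCompareModels:
    def test_identical_models_are_indistinguishable(self):
        y = pd.Series(np.arange(10.0))
        pred = y + 1.0
        t, p = compare_models(pred, pred.copy(), y)
        assert t == 0.0 and p == 1.0

    def test_constant_error_difference_is_degenerate_certain(self):
        # |error_A| = |error_B| - 1 everywhere: zero-variance differences
        y = pd.Series(np.zeros(100))
        pred_a = pd.Series(np.ones(100))
        pred_b = pd.Series(np.full(100, 2.0))
        t, p = compare_models(pred_a, pred_b, y)
        assert t == -np.inf and p == 0.0

    def test_null_calibration(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = pd.Series(np.zeros(80))
            a = pd.Series(rng.standard_normal(80))
            b = pd.Series(rng.standard_normal(80))
            _, p = compare_models(a, b, y)
            hits += p < 0.05
        assert hits <= 5  # ~5% expected; binomial slack

    def test_mismatched_county_sets_raise(self):
        a = pd.Series([1.0, 2.0], index=["a", "b"])
        b = pd.Series([1.0, 2.0], index=["a", "c"])
        with pytest.raises(ValueError):
            compare_models(a, b, pd.Series([0.0, 0.0], index=["a", "b"]))
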