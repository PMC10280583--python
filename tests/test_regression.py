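"""MLR/PLSR/PCR contracts and cross-validated component selection."""

import numpy as np
import pytest

from nircae.regression import (
    CVResult,
    LatentMLR,
    PCRegressor,
    PLSRegressor,
    fit_mlr,
    fit_pcr,
    fit_plsr,
    load_model,
    select_components_cv,
)


def _ols_predictions(X, y, X_new):
    """Independent oracle: normal-equation least squares with intercept."""
    D = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    return np.column_stack([np.ones(len(X_new)), X_new]) @ beta


class TestLatentMLR:
    def test_exact_recovery_noiseless(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [2.0, 0.5]])
        y = 2 * X[:, 0] - X[:, 1] + 5
        m = fit_mlr(X, y)
        np.testing.assert_allclose(m.coef_, [2, -1], atol=1e-10)
        np.testing.assert_allclose(m.intercept_, 5, atol=1e-10)

    def test_residual_orthogonality(self, rng):
        X = rng.normal(size=(60, 32))
        y = X @ rng.normal(size=32) + rng.normal(0, 0.1, 60)
        m = fit_mlr(X, y)
        resid = y - m.predict(X)
        assert abs(resid.sum()) < 1e-8  # orthogonal to the constant column
        assert np.abs(X.T @ resid).max() < 1e-8

    def test_underdetermined_rejected(self, rng):
        X = rng.normal(size=(10, 10))
        with pytest.raises(ValueError, match="more samples"):
            fit_mlr(X, rng.normal(size=10))

    def test_collinear_columns_named(self, rng):
        X = rng.normal(size=(30, 4))
        X[:, 3] = 2 * X[:, 1]  # exact collinearity
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_mlr(X, rng.normal(size=30))

    def test_minimum_norm_fallback_when_requested(self, rng):
        X = rng.normal(size=(30, 4))
        X[:, 3] = 2 * X[:, 1]
        y = X[:, 0] + rng.normal(0, 0.1, 30)
        m = LatentMLR(allow_rank_deficient=True).fit(X, y)
        assert np.isfinite(m.predict(X)).all()


class TestPLSR:
    def test_full_components_equal_ols(self, rng):
        X = rng.normal(size=(10, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + 7 + rng.normal(0, 0.1, 10)
        m = fit_plsr(X, y, 4)
        np.testing.assert_allclose(m.predict(X), _ols_predictions(X, y, X),
                                   atol=1e-8)

    def test_single_factor_recovery(self, rng):
        X = rng.normal(size=(20, 5))
        # exact one-component fit requires y to span a single X direction
        X1 = np.zeros((20, 5))
        X1[:, 0] = rng.normal(size=20)
        y1 = 3.0 * X1[:, 0]
        m1 = fit_plsr(X1 + 0.0, y1, 1)
        rmse_train = np.sqrt(np.mean((y1 - m1.predict(X1)) ** 2))
        assert rmse_train < 1e-10

    def test_score_orthogonality_wide_matrix(self, rng):
        X = rng.normal(size=(60, 700))
        y = X[:, :3] @ np.ones(3) + rng.normal(0, 0.1, 60)
        m = fit_plsr(X, y, 10)
        T = m.x_scores_
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_constant_target_rejected(self, rng):
        with pytest.raises(ValueError, match="zero variance"):
            fit_plsr(rng.normal(size=(10, 3)), np.ones(10), 2)


class TestPCR:
    def test_all_components_equal_ols(self, rng):
        X = rng.normal(size=(12, 5))
        y = X @ rng.normal(size=5) + 2 + rng.normal(0, 0.1, 12)
        m = fit_pcr(X, y, 5)
        np.testing.assert_allclose(m.predict(X), _ols_predictions(X, y, X),
                                   atol=1e-8)

    def test_dominant_direction_variance(self, rng):
        v = rng.normal(size=6)
        v /= np.linalg.norm(v)
        t = rng.normal(0, 10, size=40)
        X = np.outer(t, v) + rng.normal(0, 0.05, size=(40, 6))
        m = fit_pcr(X, t, 1)
        assert m.explained_variance_ratio_[0] > 0.99

    def test_scores_uncorrelated(self, rng):
        X = rng.normal(size=(30, 8))
        m = fit_pcr(X, X @ rng.normal(size=8), 5)
        gram = m.scores_.T @ m.scores_
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8


class TestFamilyAgreement:
    def test_all_families_reduce_to_ols_on_full_rank_design(self, rng):
        X = rng.normal(size=(25, 6))
        y = X @ rng.normal(size=6) + 1.5 + rng.normal(0, 0.2, 25)
        X_new = rng.normal(size=(10, 6))
        preds = [
            fit_mlr(X, y).predict(X_new),
            fit_plsr(X, y, 6).predict(X_new),
            fit_pcr(X, y, 6).predict(X_new),
        ]
        for p in preds[1:]:
            np.testing.assert_allclose(p, preds[0], atol=1e-6)

    def test_prediction_is_affine(self, rng):
        X = rng.normal(size=(30, 5))
        y = X @ rng.normal(size=5) + rng.normal(0, 0.1, 30)
        m = fit_plsr(X, y, 3)
        x0 = rng.normal(size=(1, 5))
        d = rng.normal(size=(1, 5))
        base = m.predict(x0)
        np.testing.assert_allclose(
            m.predict(x0 + 2 * d) - base, 2 * (m.predict(x0 + d) - base),
            atol=1e-9)


class TestComponentSelection:
    def test_known_factor_count_recovered(self):
        """Three latent factors + small noise: CV concentrates near k=3."""
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            F = rng.normal(size=(60, 3))
            A = rng.normal(size=(3, 20))
            X = F @ A + rng.normal(0, 0.02, size=(60, 20))
            y = F @ np.array([1.0, -1.0, 0.5]) + rng.normal(0, 0.02, 60)
            cv = select_components_cv(X, y, "plsr", k_max=10, folds=5,
                                      seed=seed)
            hits += cv.selected == 3
        assert hits >= 3

    def test_deterministic_for_seed(self, rng):
        X = rng.normal(size=(40, 8))
        y = X @ rng.normal(size=8) + rng.normal(0, 0.1, 40)
        a = select_components_cv(X, y, "pcr", k_max=8, seed=5)
        b = select_components_cv(X, y, "pcr", k_max=8, seed=5)
        assert a == b

    def test_selected_minimizes_with_smaller_k_tiebreak(self, rng):
        X = rng.normal(size=(40, 8))
        y = X @ rng.normal(size=8) + rng.normal(0, 0.1, 40)
        cv = select_components_cv(X, y, "plsr", k_max=8, seed=1)
        best = min(cv.rmse_per_k.values())
        assert cv.rmse_per_k[cv.selected] == best
        for k in range(1, cv.selected):
            assert cv.rmse_per_k[k] > best

    def test_constant_target_rejected(self, rng):
        with pytest.raises(ValueError, match="zero variance"):
            select_components_cv(rng.normal(size=(20, 5)), np.ones(20),
                                 "plsr")

    def test_k_max_clipped_with_warning(self, rng):
        X = rng.normal(size=(10, 20))
        y = X[:, 0] + rng.normal(0, 0.1, 10)
        with pytest.warns(UserWarning, match="clipped"):
            cv = select_components_cv(X, y, "plsr", k_max=10, folds=5)
        assert max(cv.rmse_per_k) <= 7  # smallest training fold has 8 rows

    def test_unknown_family_rejected(self, rng):
        with pytest.raises(ValueError, match="family"):
            select_components_cv(rng.normal(size=(20, 5)),
                                 rng.normal(size=20), "mlr")


class TestSerialization:
    @pytest.mark.parametrize("fit", [
        lambda X, y: fit_mlr(X[:, :4], y),
        lambda X, y: fit_plsr(X, y, 3),
        lambda X, y: fit_pcr(X, y, 3),
    ])
    def test_json_roundtrip(self, tmp_path, rng, fit):
        X = rng.normal(size=(30, 6))
        y = X @ rng.normal(size=6) + 2 + rng.normal(0, 0.1, 30)
        m = fit(X, y)
        path = tmp_path / "model.json"
        m.save(path)
        back = load_model(path)
        X_new = rng.normal(size=(5, m.coef_.size))
        np.testing.assert_allclose(back.predict(X_new), m.predict(X_new),
                                   atol=1e-12)
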