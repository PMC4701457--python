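"""Relevance vector regression core: kernels, fits, oracles, invariants."""

import numpy as np
import pytest

from patternreg import (fit_krr, fit_rvr, linear_kernel, predict_krr,
                        predict_rvr, primal_weights)
from patternreg.rvm import RVRModel

from conftest import linear_toy


class TestLinearKernel:
    def test_identical_rows_center_to_zero(self):
        X = np.tile([1.0, 2.0, 3.0], (4, 1))
        km = linear_kernel(X)
        np.testing.assert_allclose(km.K, 0.0, atol=1e-12)

    def test_hand_arithmetic(self):
        km = linear_kernel(np.array([[1.0], [3.0]]))
        np.testing.assert_allclose(km.centering_mean, [2.0])
        np.testing.assert_allclose(km.K, [[1.0, -1.0], [-1.0, 1.0]])

    def test_matches_bruteforce_dot_products(self, rng):
        X = rng.standard_normal((6, 20))
        km = linear_kernel(X)
        Xc = X - X.mean(axis=0)
        expected = np.empty((6, 6))
        for i in range(6):
            for j in range(6):
                expected[i, j] = float(np.dot(Xc[i], Xc[j]))
        np.testing.assert_allclose(km.K, expected, atol=1e-10)

    def test_train_kernel_symmetric_psd(self, rng):
        X = rng.standard_normal((12, 30))
        K = linear_kernel(X).K
        assert np.max(np.abs(K - K.T)) < 1e-10
        eig = np.linalg.eigvalsh(K)
        assert eig.min() >= -1e-8 * eig.max()

    def test_cross_kernel_uses_training_mean(self, rng):
        Xtr = rng.standard_normal((5, 7))
        Xte = rng.standard_normal((3, 7))
        km = linear_kernel(Xtr, Xte)
        mu = Xtr.mean(axis=0)
        np.testing.assert_allclose(km.K, (Xte - mu) @ (Xtr - mu).T)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            linear_kernel(rng.standard_normal((4, 3)),
                          rng.standard_normal((2, 5)))


class TestFitRVR:
    def test_constant_target_predicts_offset(self, rng):
        K = linear_kernel(rng.standard_normal((8, 5)))
        y = np.full(8, 7.0)
        model = fit_rvr(K, y)
        assert model.all_pruned
        np.testing.assert_allclose(predict_rvr(model, K.K), 7.0)

    def test_frozen_hyperparameters_match_closed_form(self, rng):
        # oracle: mu = beta (A + beta Phi^T Phi)^-1 Phi^T yc
        for n, V in [(6, 3), (12, 8), (20, 10)]:
            X = rng.standard_normal((n, V))
            y = rng.standard_normal(n) * 5 + 3
            km = linear_kernel(X)
            model = fit_rvr(km, y, max_iter=0, alpha_init=1.0, beta_init=100.0)
            Phi = np.concatenate([np.ones((n, 1)), km.K], axis=1)
            yc = y - y.mean()
            mu_ref = 100.0 * np.linalg.solve(
                np.eye(n + 1) + 100.0 * Phi.T @ Phi, Phi.T @ yc)
            np.testing.assert_allclose(model.mu, mu_ref, atol=1e-8)

    def test_noiseless_interpolation(self):
        X, y, _ = linear_toy(12, 5, noise_sd=0.0, seed=3)
        km = linear_kernel(X)
        model = fit_rvr(km, y)
        yhat = predict_rvr(model, km.K)
        assert np.max(np.abs(yhat - y)) < 1e-6

    def test_loo_predictions_match_ols_oracle(self):
        # held-out RVR predictions vs per-fold ordinary least squares
        X, y, _ = linear_toy(50, 5, noise_sd=0.01, seed=5)
        rvr_pred = np.empty(50)
        ols_pred = np.empty(50)
        for i in range(50):
            tr = np.delete(np.arange(50), i)
            km = linear_kernel(X[tr])
            model = fit_rvr(km, y[tr])
            kx = linear_kernel(X[tr], X[[i]])
            rvr_pred[i] = predict_rvr(model, kx)[0]
            A = np.concatenate([np.ones((49, 1)), X[tr]], axis=1)
            coef, *_ = np.linalg.lstsq(A, y[tr], rcond=None)
            ols_pred[i] = coef[0] + X[i] @ coef[1:]
        assert np.corrcoef(rvr_pred, ols_pred)[0, 1] > 0.99

    def test_kernel_collapsed_to_zero_predicts_mean(self, rng):
        X = np.tile(rng.standard_normal(4), (6, 1))  # identical subjects
        y = rng.standard_normal(6)
        km = linear_kernel(X)
        model = fit_rvr(km, y)
        np.testing.assert_allclose(predict_rvr(model, np.zeros((3, 6))),
                                   y.mean(), atol=1e-8)

    def test_input_validation(self, rng):
        K = linear_kernel(rng.standard_normal((5, 3)))
        with pytest.raises(ValueError, match="at least 3"):
            fit_rvr(np.zeros((2, 2)), np.zeros(2))
        with pytest.raises(ValueError, match="square"):
            fit_rvr(np.zeros((3, 4)), np.zeros(3))
        with pytest.raises(ValueError, match="finite"):
            fit_rvr(K, np.array([1.0, np.nan, 2.0, 0.0, 1.0]))

    def test_sparsity_bounds(self):
        X, y, _ = linear_toy(100, 20, noise_sd=0.5, seed=8)
        model = fit_rvr(linear_kernel(X), y)
        assert len(model.active_idx) <= 101
        assert len(model.active_idx) < 100  # strict pruning occurs

    def test_evidence_nondecreasing(self):
        for seed in range(5):
            X, y, _ = linear_toy(40, 20, noise_sd=0.5, seed=seed)
            model = fit_rvr(linear_kernel(X), y)
            steps = np.diff(model.evidence)
            assert steps.min() > -1e-6

    def test_training_order_invariance(self, rng):
        X, y, _ = linear_toy(12, 6, noise_sd=0.2, seed=11)
        Xte = rng.standard_normal((4, 6))
        km = linear_kernel(X)
        pred = predict_rvr(fit_rvr(km, y), linear_kernel(X, Xte).K)
        perm = rng.permutation(12)
        kmp = linear_kernel(X[perm])
        pred_p = predict_rvr(fit_rvr(kmp, y[perm]),
                             linear_kernel(X[perm], Xte).K)
        np.testing.assert_allclose(pred, pred_p, atol=1e-10)

    def test_serialization_round_trip(self, tmp_path):
        X, y, _ = linear_toy(15, 4, noise_sd=0.3, seed=2)
        model = fit_rvr(linear_kernel(X), y)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = RVRModel.load(path)
        np.testing.assert_array_equal(loaded.mu, model.mu)
        np.testing.assert_array_equal(loaded.active_idx, model.active_idx)
        assert loaded.y_offset == model.y_offset
        K = linear_kernel(X).K
        np.testing.assert_allclose(predict_rvr(loaded, K),
                                   predict_rvr(model, K))


class TestPredictRVR:
    def test_column_mismatch(self, rng):
        X, y, _ = linear_toy(8, 3, noise_sd=0.1, seed=1)
        model = fit_rvr(linear_kernel(X), y)
        with pytest.raises(ValueError, match="columns"):
            predict_rvr(model, np.zeros((2, 5)))

    def test_manual_reconstruction_toy(self):
        # oracle: rebuild yhat by hand from (mu, active_idx, y_offset)
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        y = np.array([1.0, 2.0, 3.0])
        km = linear_kernel(X)
        model = fit_rvr(km, y, max_iter=0, alpha_init=0.5, beta_init=50.0)
        K_cross = linear_kernel(X, np.array([[0.5, 0.5]])).K
        got = predict_rvr(model, K_cross)
        Phi_test = np.concatenate([np.ones((1, 1)), K_cross], axis=1)
        by_hand = model.y_offset + float(
            Phi_test[0, model.active_idx] @ model.mu)
        assert got[0] == pytest.approx(by_hand, abs=1e-12)


class TestPrimalWeights:
    def test_offset_only_model_gives_zero_weights(self, rng):
        X = rng.standard_normal((6, 4))
        model = fit_rvr(linear_kernel(X), np.full(6, 2.0))
        np.testing.assert_array_equal(primal_weights(model, X - X.mean(0)),
                                      np.zeros(4))

    def test_single_relevance_vector_by_hand(self):
        model = RVRModel(
            alpha=np.array([1.0]), beta=1.0, mu=np.array([2.0]),
            Sigma_diag=np.array([0.1]), active_idx=np.array([1]),
            y_offset=0.0, n_train=3, n_iter=1, converged=True,
            evidence=np.empty(0),
        )
        Xc = np.array([[1.0, 0.0, -1.0], [5.0, 5.0, 5.0], [0.0, 0.0, 0.0]])
        np.testing.assert_allclose(primal_weights(model, Xc), [2.0, 0.0, -2.0])

    def test_dual_primal_agreement(self, rng):
        # oracle: dual-form prediction on 10 random test points
        X, y, _ = linear_toy(20, 6, noise_sd=0.2, seed=9)
        km = linear_kernel(X)
        model = fit_rvr(km, y)
        Xc = X - km.centering_mean
        w = primal_weights(model, Xc)
        mu_bias = (model.mu[model.active_idx == 0].sum()
                   if 0 in model.active_idx else 0.0)
        Xte = rng.standard_normal((10, 6))
        dual = predict_rvr(model, linear_kernel(X, Xte).K)
        primal = model.y_offset + (Xte - km.centering_mean) @ w + mu_bias
        np.testing.assert_allclose(dual, primal, atol=1e-8)


class TestKRR:
    def test_large_lambda_shrinks_to_mean(self, rng):
        X, y, _ = linear_toy(10, 4, noise_sd=0.1, seed=4)
        km = linear_kernel(X)
        model = fit_krr(km, y, ridge_lambda=1e12)
        np.testing.assert_allclose(predict_krr(model, km.K), y.mean(),
                                   atol=1e-6)

    def test_hand_solve_3x3(self):
        K = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 1.0], [0.0, 1.0, 2.0]])
        y = np.array([1.0, 2.0, 3.0])
        model = fit_krr(K, y, ridge_lambda=1.0)
        expected = np.linalg.solve(K + np.eye(3), y - 2.0)
        np.testing.assert_allclose(model.dual_coef, expected, atol=1e-12)

    def test_lambda_must_be_positive(self):
        with pytest.raises(ValueError):
            fit_krr(np.eye(3), np.zeros(3), ridge_lambda=0.0)

    def test_krr_and_rvr_agree_on_signal_fixture(self):
        # both near-linear decoders should perform comparably when the
        # signal is strong (the no-difference regime)
        X, y, _ = linear_toy(60, 30, noise_sd=0.5, seed=6)
        r_vals = {}
        for name in ("rvr", "krr"):
            preds = np.empty(60)
            for i in range(60):
                tr = np.delete(np.arange(60), i)
                km = linear_kernel(X[tr])
                kx = linear_kernel(X[tr], X[[i]]).K
                if name == "rvr":
                    preds[i] = predict_rvr(fit_rvr(km, y[tr]), kx)[0]
                else:
                    lam = 0.01 * np.trace(km.K) / len(tr)
                    preds[i] = predict_krr(fit_krr(km, y[tr], lam), kx)[0]
            r_vals[name] = np.corrcoef(y, preds)[0, 1]
        assert abs(r_vals["rvr"] - r_vals["krr"]) < 0.1
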