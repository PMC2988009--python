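"""LS-SVM, Bayesian posterior, KLR/MKLR and hyperparameter tuning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import polyrisk as pr
from polyrisk.data import OUTCOMES
from polyrisk.kernels import (
    KLR,
    KernelError,
    KernelSpec,
    LSSVM,
    MKLR,
    kernel_matrix,
    tune_cv,
)


class TestKernelMatrix:
    def test_gaussian_diagonal_is_one(self, rng):
        X = rng.normal(size=(6, 3))
        K = kernel_matrix(X, X, KernelSpec("gaussian", 1.5))
        assert np.allclose(np.diag(K), 1.0)

    def test_linear_basis_vectors_identity(self):
        E = np.eye(4)
        assert np.allclose(kernel_matrix(E, E, KernelSpec("linear")), np.eye(4))

    def test_gaussian_hand_value(self):
        K = kernel_matrix([[0.0, 0.0]], [[1.0, 1.0]], KernelSpec("gaussian", np.sqrt(2)))
        assert K[0, 0] == pytest.approx(np.exp(-1.0))

    def test_dimension_mismatch_and_bad_sigma(self):
        with pytest.raises(KernelError):
            kernel_matrix(np.zeros((2, 3)), np.zeros((2, 2)), KernelSpec("linear"))
        with pytest.raises(KernelError):
            KernelSpec("gaussian", -1.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(2, 12), st.floats(0.5, 4.0))
    def test_gaussian_psd(self, n, sigma):
        X = np.random.default_rng(n).normal(size=(n, 3))
        K = kernel_matrix(X, X, KernelSpec("gaussian", sigma))
        assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestLSSVM:
    def test_two_point_symmetry(self):
        fit = LSSVM(np.array([[1.0], [-1.0]]), np.array([1.0, -1.0]), 1.0,
                    standardize=False).fit()
        assert fit.b == pytest.approx(0.0, abs=1e-10)
        f = fit.latent(np.array([[1.0], [-1.0]]), raw=True)
        assert f[0] > 0 > f[1]

    def test_kkt_residual_and_constraint(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.where(rng.random(30) < 0.5, -1.0, 1.0)
        fit = LSSVM(X, y, 3.0, KernelSpec("gaussian", 2.0)).fit()
        assert fit.kkt_residual() <= 1e-8
        assert abs(fit.sum_alpha_y) <= 1e-8

    def test_xor_gaussian_separates(self):
        X = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        y = np.array([1.0, 1.0, -1.0, -1.0])
        fit = LSSVM(X, y, 10.0, KernelSpec("gaussian", 1.0), standardize=False).fit()
        assert np.all(np.sign(fit.latent(X, raw=True)) == y)

    def test_fast_loo_equals_naive(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.where(rng.random(20) < 0.5, -1.0, 1.0)
        spec = KernelSpec("gaussian", 2.0)
        fit = LSSVM(X, y, 2.0, spec, standardize=False).fit()
        loo = fit.loo_latent()
        naive = []
        for i in range(20):
            idx = np.delete(np.arange(20), i)
            sub = LSSVM(X[idx], y[idx], 2.0, spec, standardize=False).fit()
            naive.append(sub.latent(X[i:i + 1], raw=True)[0])
        assert np.max(np.abs(loo - np.array(naive))) <= 1e-8

    def test_loo_reorder_invariance(self, rng):
        X = rng.normal(size=(15, 2))
        y = np.where(rng.random(15) < 0.5, -1.0, 1.0)
        perm = rng.permutation(15)
        a = LSSVM(X, y, 1.0, standardize=False).fit().loo_latent()
        b = LSSVM(X[perm], y[perm], 1.0, standardize=False).fit().loo_latent()
        assert np.allclose(a[perm], b, atol=1e-9)

    def test_posterior_prior_when_uninformative(self, rng):
        # both classes share the same latent distribution => posterior = prior
        X = rng.normal(size=(200, 2))
        y = np.where(rng.random(200) < 0.5, -1.0, 1.0)  # labels independent of X
        fit = LSSVM(X, y, 1.0).fit()
        fit.latent_stats = {"pos": (0.0, 1.0), "neg": (0.0, 1.0)}
        p = fit.posterior(X, priors=(0.25, 0.75))
        assert np.allclose(p, 0.75)

    def test_posterior_hand_bayes(self):
        # latent means +-1, common SD 1, prior 0.75 positive, f = 0
        fit = LSSVM(np.array([[1.0], [-1.0]]), np.array([1.0, -1.0]), 1.0,
                    standardize=False).fit()
        fit.latent_stats = {"pos": (1.0, 1.0), "neg": (-1.0, 1.0)}
        fit.alpha = np.zeros(2)  # forces latent f = b = 0
        fit.b = 0.0
        p = fit.posterior(np.array([[0.0]]), priors=(0.25, 0.75))
        assert p[0] == pytest.approx(0.75, abs=1e-10)

    def test_posterior_in_unit_interval(self, rng):
        X = rng.normal(size=(60, 3))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=60) > 0, 1.0, -1.0)
        fit = LSSVM(X, y, 5.0).fit()
        p = fit.posterior(rng.normal(size=(100, 3)))
        assert np.all((p >= 0) & (p <= 1))


class TestKLRAndMKLR:
    def test_heavy_penalty_gives_prevalence(self, rng):
        X = rng.normal(size=(60, 2))
        y = (rng.random(60) < 0.3).astype(int)
        fit = KLR(X, y, 1e8).fit()
        assert np.allclose(fit.predict(X), y.mean(), atol=1e-6)

    def test_tiny_penalty_matches_unpenalized_lr(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 2)), columns=["a", "b"])
        eta = 0.5 + X["a"] - 0.7 * X["b"]
        y = (rng.random(80) < 1 / (1 + np.exp(-eta))).astype(int)
        klr = KLR(X, y.to_numpy(), 1e-6, KernelSpec("linear")).fit()
        lr = pr.fit_logistic(X, y)
        assert np.max(np.abs(klr.predict(X) - lr.predict(X))) < 1e-3

    def test_objective_monotone_under_irls(self, rng):
        X = rng.normal(size=(50, 3))
        y = (X[:, 0] > 0).astype(int)
        model = KLR(X, y, 0.5, KernelSpec("gaussian", 2.0))
        # track the objective across refits with increasing iteration caps
        objs = [model.fit(maxiter=k).objective for k in (1, 2, 5, 20)]
        assert all(b <= a + 1e-10 for a, b in zip(objs, objs[1:]))

    def test_mklr_two_class_equals_klr(self, rng):
        X = pd.DataFrame(rng.normal(size=(70, 2)), columns=["a", "b"])
        y = (rng.random(70) < 0.4).astype(int)
        mk = MKLR(X, y, 0.7).fit()
        kl = KLR(X, y, 0.7).fit()
        assert np.max(np.abs(mk.predict(X)[1].to_numpy() - kl.predict(X))) < 1e-6

    def test_mklr_heavy_penalty_prevalences(self, rng):
        X = rng.normal(size=(80, 2))
        y = np.array(rng.choice(list(OUTCOMES), size=80, p=[0.5, 0.2, 0.2, 0.1]))
        fit = MKLR(X, y, 1e8).fit()
        probs = fit.predict(X)
        for cls in OUTCOMES:
            assert np.allclose(probs[cls], (y == cls).mean(), atol=1e-5)

    def test_mklr_rows_sum_to_one(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.array(rng.choice(list(OUTCOMES), size=40, p=[0.4, 0.3, 0.2, 0.1]))
        fit = MKLR(X, y, 2.0, KernelSpec("gaussian", 3.0)).fit()
        P = fit.predict(rng.normal(size=(200, 3))).to_numpy()
        assert np.all(P >= 0)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)


class TestTuneCV:
    @staticmethod
    def _fp(params, Xtr, ytr, Xva):
        fit = LSSVM(Xtr, 2.0 * ytr - 1.0, params["gamma"]).fit()
        return fit.posterior(Xva)

    def test_single_point_grid(self, rng):
        X = rng.normal(size=(40, 2))
        y = (X[:, 0] > 0).astype(int)
        best, _ = tune_cv(self._fp, [{"gamma": 1.0}], X, y, folds=4, seed=0)
        assert best == {"gamma": 1.0}

    def test_tie_breaks_to_most_regularized(self, rng):
        y = (rng.random(40) < 0.5).astype(int)

        def const_fp(params, Xtr, ytr, Xva):
            return np.full(len(Xva), 0.5)

        grid = [{"gamma": g, "sigma": s} for g in (0.1, 10.0) for s in (1.0, 4.0)]
        best, _ = tune_cv(const_fp, grid, rng.normal(size=(40, 2)), y, seed=0)
        assert best == {"gamma": 0.1, "sigma": 4.0}

    def test_signal_beats_degenerate_endpoint(self, rng):
        n = 120
        X = rng.normal(size=(n, 2))
        y = (X[:, 0] + 0.5 * rng.normal(size=n) > 0).astype(int)
        grid = [{"gamma": g} for g in (1e-6, 1.0, 10.0)]
        best, info = tune_cv(self._fp, grid, X, y, folds=5, seed=1)
        assert best["gamma"] != 1e-6
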