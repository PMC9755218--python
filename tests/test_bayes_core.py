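"""Sparse Bayesian core: evidence, BCSL greedy, ridge."""

import itertools

import numpy as np
import pytest
from scipy import integrate, optimize

from sparsedyn import LinearSystem, SolverOptions, bcsl_fit, log_evidence, ridge_fit
from sparsedyn.bayes_core import _profile_lambda

from conftest import make_sparse_system


def oracle_max_evidence(phi, g, n_starts=3, maxiter=2500):
    """Exhaustive-support multi-start maximisation of the log evidence.

    Independent of the greedy path: for every support subset, (log γ, log β)
    are optimised numerically with λ at its stationary profile.
    """
    N, K = phi.shape
    system = LinearSystem(phi, g)
    rng = np.random.default_rng(0)
    best = -np.inf
    for L in range(K + 1):
        for supp in itertools.combinations(range(K), L):
            def negev(x):
                gamma = np.zeros(K)
                if L:
                    gamma[list(supp)] = np.exp(np.clip(x[:L], -40, 40))
                beta = np.exp(np.clip(x[L], -40, 40))
                lam = _profile_lambda(float(gamma.sum()), L)
                try:
                    return -log_evidence(system, gamma, lam, beta)
                except Exception:
                    return 1e30
            for _ in range(n_starts):
                x0 = rng.standard_normal(L + 1) * 2.0
                x0[L] = np.log(1.0 / np.var(g)) + rng.standard_normal()
                res = optimize.minimize(
                    negev, x0, method="Nelder-Mead",
                    options={"maxiter": maxiter, "fatol": 1e-13, "xatol": 1e-11},
                )
                best = max(best, -float(res.fun))
    return best


class TestBCSL:
    def test_orthonormal_design_exact_signal(self):
        m = bcsl_fit(LinearSystem(np.eye(3), np.array([1.0, 0.0, 0.0])))
        assert list(m.support) == [0]
        assert m.weights == pytest.approx([1.0, 0.0, 0.0], abs=1e-8)

    def test_single_column_exact_fit_underdetermined(self, rng):
        # 2x4: g is exactly 3 * column 1 — the single-column zero-residual
        # support is the enumeration oracle's answer
        phi = rng.standard_normal((2, 4))
        g = 3.0 * phi[:, 1]
        m = bcsl_fit(LinearSystem(phi, g))
        assert list(m.support) == [1]
        assert m.weights[1] == pytest.approx(3.0, abs=1e-6)

    def test_noisy_sparse_recovery(self, sparse_system):
        # exhaustive-support least squares with a BIC-style comparison picks
        # {1, 4}; BCSL must agree and land within 3 noise sd of the truth
        system, w_true = sparse_system
        m = bcsl_fit(system)
        assert list(m.support) == [1, 4]
        for i in m.support:
            assert abs(m.weights[i] - w_true[i]) < 3 * 0.01

    def test_noise_free_exact_recovery(self):
        # k <= 3 true columns, well-conditioned: support and coefficients exact
        rng = np.random.default_rng(7)
        phi = rng.standard_normal((40, 6))
        w = np.zeros(6)
        w[[0, 3, 5]] = [1.5, -2.2, 0.7]
        m = bcsl_fit(LinearSystem(phi, phi @ w))
        assert list(m.support) == [0, 3, 5]
        assert m.weights == pytest.approx(w, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_oracle_equivalence(self, seed):
        """The greedy fit attains the globally maximal evidence (small K)."""
        rng = np.random.default_rng(seed)
        N, K = 25, 4
        phi = rng.standard_normal((N, K))
        phi /= np.linalg.norm(phi, axis=0)
        w = np.zeros(K)
        w[rng.choice(K, 2, replace=False)] = rng.standard_normal(2) * 2.0
        g = phi @ w + 0.05 * rng.standard_normal(N)
        m = bcsl_fit(LinearSystem(phi, g))
        oracle = oracle_max_evidence(phi, g)
        assert m.evidence >= oracle - 1e-6

    def test_rescaling_consistency(self):
        # fitting columns at wildly different scales reports identical
        # original-scale weights as fitting the pre-normalised system
        rng = np.random.default_rng(11)
        phi = rng.standard_normal((60, 5))
        w = np.zeros(5)
        w[[1, 3]] = [2.0, -0.5]
        g = phi @ w + 0.01 * rng.standard_normal(60)
        scales = np.array([1.0, 1e4, 1e-3, 5.0, 100.0])
        m_raw = bcsl_fit(LinearSystem(phi, g))
        m_scaled = bcsl_fit(LinearSystem(phi * scales, g))
        assert m_scaled.weights * scales == pytest.approx(m_raw.weights, abs=1e-10)

    def test_deterministic(self, sparse_system):
        system, _ = sparse_system
        a = bcsl_fit(system)
        b = bcsl_fit(system)
        assert np.array_equal(a.weights, b.weights)
        assert a.evidence == b.evidence

    def test_rejects_nonfinite_design(self):
        phi = np.ones((4, 2))
        phi[1, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            LinearSystem(phi, np.ones(4))


class TestRidge:
    def test_alpha_zero_square_invertible_is_least_squares(self, rng):
        phi = rng.standard_normal((5, 5))
        g = rng.standard_normal(5)
        m = ridge_fit(LinearSystem(phi, g), 0.0)
        assert phi @ m.weights == pytest.approx(g, abs=1e-8)

    def test_large_alpha_shrinks_to_zero(self, sparse_system):
        system, _ = sparse_system
        m = ridge_fit(system, 1e12)
        assert np.all(np.abs(m.weights) < 1e-6)

    def test_matches_closed_form_normal_equations(self, rng):
        phi = rng.standard_normal((10, 3))
        w = np.array([1.0, -2.0, 0.5])
        g = phi @ w
        alpha = 0.1
        norms = np.linalg.norm(phi, axis=0)
        phin = phi / norms
        w_expect = np.linalg.solve(phin.T @ phin + alpha * np.eye(3), phin.T @ g) / norms
        m = ridge_fit(LinearSystem(phi, g), alpha)
        assert m.weights == pytest.approx(w_expect, abs=1e-10)

    def test_rank_deficient_alpha_zero_flags_minimum_norm(self, rng):
        phi = rng.standard_normal((6, 3))
        phi = np.column_stack([phi, phi[:, 0]])  # duplicate column
        m = ridge_fit(LinearSystem(phi, phi[:, 0]), 0.0)
        assert m.meta.get("minimum_norm") is True


class TestLogEvidence:
    def test_null_model_is_gaussian_noise_likelihood(self, rng):
        phi = rng.standard_normal((12, 3))
        g = rng.standard_normal(12)
        beta = 2.5
        ev = log_evidence(LinearSystem(phi, g), np.zeros(3), 0.0, beta)
        expect = -0.5 * (12 * np.log(2 * np.pi / beta) + beta * float(g @ g))
        assert ev == pytest.approx(expect, abs=1e-10)

    def test_one_column_matches_quadrature(self, rng):
        # marginalising the weight numerically over its N(0, γ) prior must
        # reproduce the closed-form Gaussian marginal
        phi = rng.standard_normal((8, 1))
        g = rng.standard_normal(8)
        gamma, beta = 0.7, 1.3
        system = LinearSystem(phi, g)
        ev = log_evidence(system, np.array([gamma]), 0.0, beta)

        def integrand(w):
            resid = g - phi[:, 0] * w
            loglik = -0.5 * (8 * np.log(2 * np.pi / beta) + beta * float(resid @ resid))
            logprior = -0.5 * (np.log(2 * np.pi * gamma) + w * w / gamma)
            return np.exp(loglik + logprior)

        val, _ = integrate.quad(integrand, -30, 30)
        assert ev == pytest.approx(np.log(val), abs=1e-8)

    def test_invariant_under_column_permutation(self, rng):
        phi = rng.standard_normal((15, 4))
        g = rng.standard_normal(15)
        gamma = np.array([0.5, 0.0, 2.0, 1.0])
        perm = [2, 0, 3, 1]
        ev1 = log_evidence(LinearSystem(phi, g), gamma, 0.8, 2.0)
        ev2 = log_evidence(LinearSystem(phi[:, perm], g), gamma[perm], 0.8, 2.0)
        assert ev1 == pytest.approx(ev2, abs=1e-10)

    def test_rejects_bad_hyperparameters(self, rng):
        system = LinearSystem(rng.standard_normal((5, 2)), rng.standard_normal(5))
        with pytest.raises(ValueError):
            log_evidence(system, np.array([-1.0, 0.0]), 0.0, 1.0)
        with pytest.raises(ValueError):
            log_evidence(system, np.zeros(2), 0.0, -1.0)
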