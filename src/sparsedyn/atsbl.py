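"""Automatic-threshold sparse learning (ATSBL).

A prior-based fit (Laplace/BCSL or Gaussian/ridge) typically leaves a number
of small, non-zero coefficients.  ATSBL removes them by wrapping the fit in a
train/test thresholding loop: the data rows are split (80/20 by default), the
model is fitted on the training rows, coefficients below a threshold ``tol``
are zeroed, the surviving support is refitted by least squares, and the
candidate is scored on the held-out rows with the L0-penalised error

    e = ||Θ_test w − g_test||² + η ||w||₀,        η = 1e-3 κ(Θ).

On improvement the threshold is raised; otherwise it is lowered and the
increment d_tol refined.  The best-scoring sparse vector over all iterations
is returned.

Thresholding acts on the unit-column-normalised coefficient scale
(|w_i|·||Θ_i||), which makes a single threshold meaningful when library
columns span many orders of magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bayes_core import LinearSystem, SolverOptions, SparseModel, bcsl_fit, ridge_fit

__all__ = ["ThresholdState", "atsbl_fit", "model_error", "hard_threshold"]


@dataclass
class ThresholdState:
    """Trace of the automatic thresholding loop."""

    tol: float
    d_tol: float
    iteration: int
    best_error: float
    best_weights: np.ndarray
    error_trace: list[float] = field(default_factory=list)
    tol_trace: list[float] = field(default_factory=list)
    eta: float = 0.0
    kappa: float = 0.0
    split_fraction: float = 0.8
    seed: int = 0


def hard_threshold(weights: np.ndarray, tol: float) -> np.ndarray:
    """Zero all entries with |w_i| < tol; others unchanged."""
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    w = np.asarray(weights, dtype=float).copy()
    w[np.abs(w) < tol] = 0.0
    return w


def model_error(
    weights: np.ndarray, test_design: np.ndarray, test_target: np.ndarray, eta: float
) -> float:
    """Penalised test error e = ||Θ_test w − g_test||² + η ||w||₀."""
    weights = np.asarray(weights, dtype=float)
    resid = np.asarray(test_target, dtype=float) - np.asarray(test_design, dtype=float) @ weights
    return float(resid @ resid) + eta * int(np.count_nonzero(weights))


def _ls_refit(phi_tr, g_tr, support, K):
    """Least-squares refit restricted to ``support`` (QR via lstsq)."""
    w = np.zeros(K)
    if len(support):
        idx = np.asarray(support)
        sol, *_ = np.linalg.lstsq(phi_tr[:, idx], g_tr, rcond=None)
        w[idx] = sol
    return w


def atsbl_fit(
    system: LinearSystem,
    prior: str = "laplace",
    d_tol0: float | None = None,
    n_iters: int = 100,
    seed: int = 0,
    split_fraction: float = 0.8,
    contiguous: bool = False,
    alpha: float = 1e-6,
    eta: float | None = None,
    options: SolverOptions | None = None,
) -> tuple[SparseModel, ThresholdState]:
    """Fit a sparse model with the automatic train/test thresholding loop.

    Parameters
    ----------
    prior : "laplace" (BCSL) or "gaussian" (ridge with ``alpha``).
    d_tol0 : initial threshold increment; defaults to max|w_init|/n_iters on
        the normalised scale of the initial unthresholded fit.
    contiguous : use a contiguous head/tail row split instead of a random
        permutation (for strongly time-correlated data).
    eta : L0 penalty; defaults to 1e-3 κ(Θ) with κ the condition number of
        the normalised design.

    Deterministic for identical inputs and seed.
    """
    if prior not in ("laplace", "gaussian"):
        raise ValueError(f"unknown prior {prior!r}")
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    N, K = system.shape
    kappa = system.condition_number()
    if eta is None:
        eta = 1e-3 * (kappa if np.isfinite(kappa) else 1e6)

    n_train = max(int(round(split_fraction * N)), 1)
    if contiguous:
        train_idx = np.arange(n_train)
        test_idx = np.arange(n_train, N)
    else:
        perm = np.random.default_rng(seed).permutation(N)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
    if len(test_idx) == 0:  # degenerate split: score on training rows
        test_idx = train_idx

    phi = system.design
    g = system.target
    norms = np.linalg.norm(phi, axis=0)
    norms = np.where(norms > 0, norms, 1.0)

    phi_n = phi / norms  # unit-norm columns: refits stay well conditioned
    phi_tr, g_tr = phi_n[train_idx], g[train_idx]
    phi_te, g_te = phi_n[test_idx], g[test_idx]

    def test_error(w_n):
        resid = g_te - phi_te @ w_n
        return float(resid @ resid) + eta * int(np.count_nonzero(w_n))

    train_system = LinearSystem(
        phi[train_idx], g_tr, system.column_names, system.column_scales
    )
    if prior == "laplace":
        fit0 = bcsl_fit(train_system, options)
    else:
        fit0 = ridge_fit(train_system, alpha)
    w0_n = fit0.weights * norms  # normalised-scale coefficients for thresholding

    best_w = w0_n.copy()
    best_e = test_error(w0_n)
    err_trace = [best_e]
    tol_trace = [0.0]

    max_w = float(np.max(np.abs(w0_n))) if np.any(w0_n) else 0.0
    d_tol = d_tol0 if d_tol0 is not None else (max_w / n_iters if max_w > 0 else 1.0)
    tol = d_tol

    cache: dict[tuple, tuple[np.ndarray, float]] = {}
    for it in range(1, n_iters + 1):
        support = tuple(np.flatnonzero(np.abs(w0_n) >= tol))
        if support in cache:
            w_ref, e = cache[support]
        else:
            w_ref = _ls_refit(phi_tr, g_tr, support, K)
            e = test_error(w_ref)
            cache[support] = (w_ref, e)
        err_trace.append(e)
        tol_trace.append(tol)
        if e <= best_e:
            best_e = e
            best_w = w_ref
            tol = tol + d_tol
        else:
            tol = max(0.0, tol - 2.0 * d_tol)
            if n_iters > it:
                d_tol = 2.0 * d_tol / (n_iters - it)
            tol = tol + d_tol

    support = np.flatnonzero(best_w != 0.0)
    # posterior statistics of the accepted support from the training refit
    uncertainty = np.zeros(K)
    post_cov = None
    beta = fit0.beta
    if len(support):
        idx = support
        resid = g_tr - phi_tr[:, idx] @ best_w[idx]
        dof = max(len(train_idx) - len(idx), 1)
        sigma2 = float(resid @ resid) / dof
        beta = 1.0 / sigma2 if sigma2 > 0 else fit0.beta
        try:
            cov_n = sigma2 * np.linalg.inv(phi_tr[:, idx].T @ phi_tr[:, idx])
            post_cov = cov_n / np.outer(norms[idx], norms[idx])
            uncertainty[idx] = np.sqrt(np.maximum(np.diag(post_cov), 0.0))
        except np.linalg.LinAlgError:
            post_cov = None

    model = SparseModel(
        weights=best_w / norms,
        support=support,
        prior=prior,
        beta=float(beta),
        gamma=fit0.gamma,
        lam=fit0.lam,
        posterior_cov=post_cov,
        uncertainty=uncertainty,
        column_names=system.column_names,
        evidence=fit0.evidence,
        meta={"eta": eta, "kappa": kappa},
    )
    state = ThresholdState(
        tol=tol,
        d_tol=d_tol,
        iteration=n_iters,
        best_error=best_e,
        best_weights=best_w / norms,
        error_trace=err_trace,
        tol_trace=tol_trace,
        eta=eta,
        kappa=kappa,
        split_fraction=split_fraction,
        seed=seed,
    )
    return model, state
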