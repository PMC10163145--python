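"""Per-expert predictive distributions and covariance-intersection fusion.

Each expert j in {C, ..., J} predicts through its correlation region psi(j):
with h = K_{A_psi A_psi}^-1 k_{A_psi, x*},

    m*_j = h' mu_psi,
    v*_j = k(x*, x*) - k_{x*, A_psi} K^-1 k_{A_psi, x*} + h' Sigma_psi h,

where (mu_psi, Sigma_psi) is the marginal posterior of the psi(j) inducing
block extracted from the sparse precision.  The expert predictions are fused
by covariance intersection with entropy-difference weights
beta_bar_j = 1/2 log(v*0 / v*_j) raised to the power Z = log(N) * C and
normalized, which keeps the fused variance between the expert variances and
the prediction continuous across expert boundaries.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from ._linalg import chol_solve
from .core import LocalConditionals, SparsePosterior
from .kernels import KernelSpec
from .partition import ExpertGraph

__all__ = [
    "posterior_subblock",
    "local_predict",
    "expert_predictions",
    "aggregation_weights",
    "aggregate",
    "predict",
]

_BETA_EPS = 1e-12
_VAR_FLOOR = 1e-300


def posterior_subblock(post: SparsePosterior, idx: np.ndarray):
    """Marginal posterior (mu_idx, Sigma_idx) of a subset of inducing outputs.

    Sigma_idx is obtained by solving Lambda with the unit columns of the
    subset (correctness-first column solves on the sparse factorization).
    """
    idx = np.asarray(idx, dtype=int)
    E = np.zeros((post.M, idx.size))
    E[idx, np.arange(idx.size)] = 1.0
    cols = post.solve(E)
    Sigma = cols[idx, :]
    Sigma = 0.5 * (Sigma + Sigma.T)
    return post.mu[idx].copy(), Sigma


def expert_predictions(X_star: np.ndarray, j: int, post: SparsePosterior,
                       conds: LocalConditionals, graph: ExpertGraph,
                       kernel: KernelSpec, subblock=None):
    """Vectorized local prediction of expert j at all query points.

    Returns ``(m, v, v0)``; ``subblock`` may carry a precomputed
    ``(mu_psi, Sigma_psi)`` pair to share the column solves across calls.
    """
    if subblock is None:
        subblock = posterior_subblock(post, graph.block_indices(graph.psi[j]))
    mu_psi, Sigma_psi = subblock
    A_psi = conds.A_psi[j]
    L_psi = conds.chol_K_psi[j]
    k_psi = kernel(A_psi, X_star)                    # (|psi| L, n)
    h = chol_solve(L_psi, k_psi)
    m = h.T @ mu_psi
    v0 = kernel.diag(X_star)
    v = v0 - np.sum(k_psi * h, axis=0) + np.sum(h * (Sigma_psi @ h), axis=0)
    return m, np.maximum(v, _VAR_FLOOR), v0


def local_predict(x_star: np.ndarray, j: int, post: SparsePosterior,
                  conds: LocalConditionals, graph: ExpertGraph,
                  kernel: KernelSpec):
    """Single-query convenience wrapper: (m*_j, v*_j, v*0) of expert j."""
    x = np.atleast_2d(np.asarray(x_star, dtype=float))
    m, v, v0 = expert_predictions(x, j, post, conds, graph, kernel)
    return float(m[0]), float(v[0]), float(v0[0])


def aggregation_weights(v0: np.ndarray, v: np.ndarray, N: int, C: int,
                        Z: float | None = None) -> np.ndarray:
    """Normalized covariance-intersection weights beta (rows sum to one).

    beta_j propto beta_bar_j^Z with beta_bar_j = 1/2 log(v0 / v_j) and
    Z = log(N) * C unless overridden.  Nonpositive entropy differences are
    clipped to a tiny epsilon before the power; if every expert clips at a
    query point the weights fall back to uniform.
    """
    v0 = np.asarray(v0, dtype=float).reshape(-1, 1)
    v = np.atleast_2d(np.asarray(v, dtype=float))
    if Z is None:
        Z = float(np.log(N) * C)
    beta_bar = 0.5 * np.log(v0 / v)
    degenerate = np.all(beta_bar <= _BETA_EPS, axis=1)
    beta_bar = np.maximum(beta_bar, _BETA_EPS)
    log_w = Z * np.log(beta_bar)
    beta = np.exp(log_w - logsumexp(log_w, axis=1, keepdims=True))
    beta[degenerate] = 1.0 / v.shape[1]
    return beta


def aggregate(m: np.ndarray, v: np.ndarray, beta: np.ndarray):
    """Covariance-intersection fusion: 1/v* = sum_j beta_j / v_j and
    m* = v* sum_j beta_j m_j / v_j."""
    m = np.atleast_2d(m)
    v = np.atleast_2d(v)
    beta = np.atleast_2d(beta)
    prec = np.sum(beta / v, axis=1)
    if np.any(prec <= 0):
        raise FloatingPointError("nonpositive fused precision; "
                                 "upstream expert variances invalid")
    v_star = 1.0 / prec
    m_star = v_star * np.sum(beta * m / v, axis=1)
    return m_star, v_star


def predict(kernel: KernelSpec, graph: ExpertGraph, conds: LocalConditionals,
            post: SparsePosterior, X_test: np.ndarray,
            Z: float | None = None, return_detail: bool = False):
    """Fused prediction over experts j = C..J at each test point.

    Returns ``(mean, var_latent, var_noisy)`` and, when requested, a detail
    dict with per-expert means/variances and the weight matrix.
    """
    X_test = np.asarray(X_test, dtype=float)
    if X_test.ndim == 1:
        X_test = X_test[:, None]
    if X_test.shape[1] != kernel.input_dim:
        raise ValueError(f"expected {kernel.input_dim} input columns, "
                         f"got {X_test.shape[1]}")
    experts = list(range(graph.C - 1, graph.J))
    n = X_test.shape[0]
    M_loc = np.empty((n, len(experts)))
    V_loc = np.empty((n, len(experts)))
    v0 = None
    for col, j in enumerate(experts):
        sub = posterior_subblock(post, graph.block_indices(graph.psi[j]))
        m, v, v0 = expert_predictions(X_test, j, post, conds, graph, kernel,
                                      subblock=sub)
        M_loc[:, col] = m
        V_loc[:, col] = v
    N = int(graph.sizes.sum())
    beta = aggregation_weights(v0, V_loc, N, graph.C, Z=Z)
    mean, var_latent = aggregate(M_loc, V_loc, beta)
    var_noisy = var_latent + kernel.noise_std ** 2
    if return_detail:
        return mean, var_latent, var_noisy, {
            "experts": experts, "m": M_loc, "v": V_loc, "beta": beta, "v0": v0}
    return mean, var_latent, var_noisy
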