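"""Approximation-quality and point-prediction metrics.

Includes the multivariate/univariate Gaussian KL divergence, the per-point
predictive KL to the full GP, the closed-form KL *differences* between two
nested correlation degrees,

    D_(C,C2)[a]     = 1/2 log |Q_C| / |Q_C2|,
    D_(C,C2)[f | a] = 1/2 log |Vbar_C| / |Vbar_C2|,

both nonnegative for C <= C2 on the same ordering, and the standard RMSE /
mean-absolute-error / 95%-coverage report.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .core import LocalConditionals

__all__ = [
    "kl_gaussian",
    "kl_gaussian_univariate",
    "predictive_kl_to_fullgp",
    "kl_difference_closed_form",
    "point_metrics",
]


def kl_gaussian(mean0, cov0, mean1, cov1) -> float:
    """KL[N(mean0, cov0) || N(mean1, cov1)] for dense SPD covariances."""
    mean0 = np.asarray(mean0, dtype=float).ravel()
    mean1 = np.asarray(mean1, dtype=float).ravel()
    cov0 = np.atleast_2d(np.asarray(cov0, dtype=float))
    cov1 = np.atleast_2d(np.asarray(cov1, dtype=float))
    k = mean0.size
    L1 = linalg.cholesky(cov1, lower=True)
    solve = lambda B: linalg.cho_solve((L1, True), B)
    tr = float(np.trace(solve(cov0)))
    diff = mean1 - mean0
    quad = float(diff @ solve(diff))
    logdet1 = 2.0 * float(np.sum(np.log(np.diag(L1))))
    L0 = linalg.cholesky(cov0, lower=True)
    logdet0 = 2.0 * float(np.sum(np.log(np.diag(L0))))
    return max(0.5 * (tr + quad - k + logdet1 - logdet0), 0.0)


def kl_gaussian_univariate(mean0, var0, mean1, var1) -> np.ndarray:
    """Vectorized KL[N(mean0, var0) || N(mean1, var1)] with positive variances."""
    mean0, var0, mean1, var1 = map(lambda a: np.asarray(a, dtype=float),
                                   (mean0, var0, mean1, var1))
    if np.any(var0 <= 0) or np.any(var1 <= 0):
        raise ValueError("variances must be positive")
    kl = 0.5 * (np.log(var1 / var0) + (var0 + (mean0 - mean1) ** 2) / var1 - 1.0)
    return np.maximum(kl, 0.0)


def predictive_kl_to_fullgp(model, fullgp, X_test, reduction: str = "sum",
                            noisy: bool = False) -> float:
    """KL of the full-GP univariate predictive to the approximate one, reduced.

    ``model`` and ``fullgp`` must expose ``predict(X) -> (mean, var, var_noisy)``.
    """
    m_q, v_q, vn_q = model.predict(X_test)[:3]
    m_p, v_p, vn_p = fullgp.predict(X_test)[:3]
    if noisy:
        v_q, v_p = vn_q, vn_p
    kl = kl_gaussian_univariate(m_p, v_p, m_q, v_q)
    if reduction == "sum":
        return float(np.sum(kl))
    if reduction == "mean":
        return float(np.mean(kl))
    raise ValueError(f"unknown reduction {reduction!r}")


def kl_difference_closed_form(conds_C: LocalConditionals,
                              conds_C2: LocalConditionals,
                              tol: float = 1e-8):
    """Closed-form KL improvements (D_a, D_f_given_a) from C to C2 >= C.

    Inputs are the local conditionals of the two models built on the *same*
    ordering with nested predecessor sets.  Diagonal entries of Vbar below
    ``tol`` in both models are treated as exact zeros (with gamma = 1 the
    projection is deterministic and Vbar vanishes up to roundoff) and
    contribute nothing to the ratio.
    """
    if len(conds_C.Q) != len(conds_C2.Q):
        raise ValueError("conditionals come from different graphs")
    d_a = 0.5 * float(np.sum(conds_C.logdet_Q) - np.sum(conds_C2.logdet_Q))
    va = np.concatenate(conds_C.Vbar)
    vb = np.concatenate(conds_C2.Vbar)
    both_zero = (va < tol) & (vb < tol)
    ratio = np.zeros_like(va)
    keep = ~both_zero
    ratio[keep] = np.log(np.maximum(va[keep], tol) / np.maximum(vb[keep], tol))
    d_f = 0.5 * float(np.sum(ratio))
    return d_a, d_f


def point_metrics(y_true, mean, var_noisy) -> dict:
    """RMSE, mean absolute error and 95% central-interval coverage."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    mean = np.asarray(mean, dtype=float).ravel()
    var_noisy = np.asarray(var_noisy, dtype=float).ravel()
    if not (y_true.size == mean.size == var_noisy.size):
        raise ValueError("length mismatch between truth and predictions")
    err = y_true - mean
    half = 1.96 * np.sqrt(var_noisy)
    return {
        "rmse": float(np.sqrt(np.mean(err ** 2))),
        "abse": float(np.mean(np.abs(err))),
        "coverage95": float(np.mean(np.abs(err) <= half)),
    }
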