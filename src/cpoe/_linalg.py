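"""Cholesky helpers with escalating jitter for near-singular kernel matrices."""

from __future__ import annotations

import numpy as np
from scipy import linalg

# Small default keeps the limiting-case equalities (full GP / FITC) tight;
# the escalation ladder below covers genuinely ill-conditioned matrices.
DEFAULT_JITTER = 1e-12
MAX_JITTER = 1e-4


class FactorizationError(np.linalg.LinAlgError):
    """Raised when a kernel matrix stays indefinite beyond the jitter ladder."""


def jittered_cholesky(K: np.ndarray, jitter: float | None = None,
                      scale: float | None = None) -> np.ndarray:
    """Lower Cholesky factor of K + jitter * scale * I.

    ``jitter`` defaults to the module-level ``DEFAULT_JITTER`` (looked up at
    call time so it can be reconfigured globally); ``scale`` defaults to the
    mean diagonal of K.  Schur complements of smooth kernels can have a tiny
    diagonal but roundoff of the size of the *parent* matrix, so callers pass
    the parent's diagonal scale there.  The jitter escalates by factors of 10
    up to ``MAX_JITTER`` if the factorization fails; beyond that a
    :class:`FactorizationError` is raised.
    """
    K = np.asarray(K, dtype=float)
    if K.size == 0:
        return np.zeros((0, 0))
    if scale is None:
        scale = float(np.mean(np.diag(K)))
    if scale <= 0:
        scale = 1.0
    eps = DEFAULT_JITTER if jitter is None else jitter
    while eps <= MAX_JITTER:
        try:
            return linalg.cholesky(K + eps * scale * np.eye(K.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            eps *= 10.0
    raise FactorizationError(
        f"matrix of size {K.shape[0]} not positive definite up to jitter {MAX_JITTER}")


def chol_solve(L: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve K x = B given the lower Cholesky factor L of K."""
    if L.size == 0:
        return np.zeros_like(B)
    return linalg.cho_solve((L, True), B)


def chol_logdet(L: np.ndarray) -> float:
    """log det K from its lower Cholesky factor."""
    return 2.0 * float(np.sum(np.log(np.diag(L))))
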