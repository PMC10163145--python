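"""Exact reference models: full GP, FITC sparse GP, and PoE-family aggregation.

These are user-facing baselines and, at small N, independent oracles for the
sparse pipeline: the full GP uses the textbook dense conditionals, FITC uses
the dense low-rank-plus-diagonal covariance, and the PoE family aggregates
exact independent local GPs.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from ._linalg import chol_logdet, chol_solve, jittered_cholesky
from .kernels import KernelSpec
from .partition import kdtree_partition
from .prediction import aggregation_weights

__all__ = ["FullGP", "FITC", "PoEBaseline",
           "fullgp_fit_predict", "fitc_fit_predict", "poe_predict"]

DENSE_GUARD = 4000


class FullGP:
    """Dense GP regression with Cholesky factorization of K_XX + sigma_n^2 I."""

    def __init__(self, kernel: KernelSpec, guard: int = DENSE_GUARD):
        self.kernel = kernel
        self.guard = guard
        self._L = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FullGP":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] > self.guard:
            raise ValueError(f"N={X.shape[0]} exceeds the dense guard "
                             f"({self.guard}) for full GP")
        self.X, self.y = X, y
        Ky = self.kernel(X, X) + self.kernel.noise_std ** 2 * np.eye(X.shape[0])
        self._L = linalg.cholesky(Ky, lower=True)
        self._alpha = chol_solve(self._L, y)
        return self

    @property
    def lml(self) -> float:
        n = self.y.size
        return -0.5 * (n * np.log(2.0 * np.pi) + chol_logdet(self._L)
                       + float(self.y @ self._alpha))

    def predict(self, X_test: np.ndarray):
        X_test = np.asarray(X_test, dtype=float)
        if X_test.ndim == 1:
            X_test = X_test[:, None]
        Ks = self.kernel(self.X, X_test)
        mean = Ks.T @ self._alpha
        W = chol_solve(self._L, Ks)
        var = self.kernel.diag(X_test) - np.sum(Ks * W, axis=0)
        var = np.maximum(var, 0.0)
        return mean, var, var + self.kernel.noise_std ** 2


class FITC:
    """Sparse GP with the FITC prior Q_ff + diag(K_ff - Q_ff) at fixed inducing inputs."""

    def __init__(self, kernel: KernelSpec, inducing: np.ndarray,
                 guard: int = DENSE_GUARD):
        self.kernel = kernel
        self.A = np.asarray(inducing, dtype=float)
        if self.A.ndim == 1:
            self.A = self.A[:, None]
        if self.A.shape[0] < 1:
            raise ValueError("need at least one inducing input")
        self.guard = guard

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FITC":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] > self.guard:
            raise ValueError(f"N={X.shape[0]} exceeds the dense guard")
        self.X, self.y = X, y
        kern = self.kernel
        self._Luu = jittered_cholesky(kern(self.A, self.A))
        Kfa = kern(X, self.A)
        Hf = chol_solve(self._Luu, Kfa.T).T          # K_fa K_aa^-1
        qff_diag = np.sum(Kfa * Hf, axis=1)
        g = np.maximum(kern.diag(X) - qff_diag, 0.0) + kern.noise_std ** 2
        # dense N x N evaluation of the FITC covariance (oracle-grade route)
        Sigma_y = Hf @ Kfa.T + np.diag(g)
        self._Ly = linalg.cholesky(
            0.5 * (Sigma_y + Sigma_y.T), lower=True)
        self._alpha = chol_solve(self._Ly, y)
        self._Kfa, self._g = Kfa, g
        return self

    @property
    def lml(self) -> float:
        n = self.y.size
        return -0.5 * (n * np.log(2.0 * np.pi) + chol_logdet(self._Ly)
                       + float(self.y @ self._alpha))

    def predict(self, X_test: np.ndarray):
        X_test = np.asarray(X_test, dtype=float)
        if X_test.ndim == 1:
            X_test = X_test[:, None]
        kern = self.kernel
        Ksa = kern(X_test, self.A)
        Hs = chol_solve(self._Luu, Ksa.T).T          # K_*a K_aa^-1
        Qsf = Hs @ self._Kfa.T                       # cross-covariance Q_*f
        mean = Qsf @ self._alpha
        W = chol_solve(self._Ly, Qsf.T)              # Sigma_y^-1 Q_f*
        var = kern.diag(X_test) - np.sum(Qsf * W.T, axis=1)
        var = np.maximum(var, 0.0)
        return mean, var, var + kern.noise_std ** 2


class PoEBaseline:
    """Independent local GP experts fused by a product-of-experts rule.

    ``mode`` is one of ``poe`` (plain product), ``gpoe`` (normalized
    entropy-difference weights, exponent ``Z``), ``bcm`` (precision sum with
    prior correction), ``minvar`` (minimum-variance expert selection).
    """

    _MODES = ("poe", "gpoe", "bcm", "minvar")

    def __init__(self, kernel: KernelSpec, B: int | None = None,
                 partition: list | None = None, mode: str = "gpoe",
                 Z: float = 1.0):
        if mode not in self._MODES:
            raise ValueError(f"unknown PoE mode {mode!r}; known: {self._MODES}")
        self.kernel = kernel
        self.B = B
        self.partition = partition
        self.mode = mode
        self.Z = Z

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PoEBaseline":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        if self.partition is None:
            if self.B is None:
                raise ValueError("either B or an explicit partition is required")
            self.partition = kdtree_partition(X, self.B)
        self._experts = []
        for idx in self.partition:
            gp = FullGP(self.kernel).fit(X[idx], y[idx])
            self._experts.append(gp)
        return self

    def predict(self, X_test: np.ndarray):
        X_test = np.asarray(X_test, dtype=float)
        if X_test.ndim == 1:
            X_test = X_test[:, None]
        n, J = X_test.shape[0], len(self._experts)
        m = np.empty((n, J))
        v = np.empty((n, J))
        for j, gp in enumerate(self._experts):
            m[:, j], v[:, j], _ = gp.predict(X_test)
        v = np.maximum(v, 1e-300)
        v0 = self.kernel.diag(X_test)

        if self.mode == "minvar":
            pick = np.argmin(v, axis=1)
            rows = np.arange(n)
            mean, var = m[rows, pick], v[rows, pick]
        elif self.mode == "poe":
            prec = np.sum(1.0 / v, axis=1)
            var = 1.0 / prec
            mean = var * np.sum(m / v, axis=1)
        elif self.mode == "bcm":
            prec = np.sum(1.0 / v, axis=1) - (J - 1) / v0
            prec = np.maximum(prec, 1.0 / v0)   # never less certain than the prior
            var = 1.0 / prec
            mean = var * np.sum(m / v, axis=1)
        else:  # gpoe
            beta = aggregation_weights(v0, v, N=n, C=1, Z=self.Z)
            prec = np.sum(beta / v, axis=1)
            var = 1.0 / prec
            mean = var * np.sum(beta * m / v, axis=1)
        return mean, var, var + self.kernel.noise_std ** 2


def fullgp_fit_predict(X, y, kernel: KernelSpec, X_test):
    """Convenience: fit a dense GP and predict; returns (mean, var, var_noisy, lml)."""
    gp = FullGP(kernel).fit(X, y)
    mean, var, var_noisy = gp.predict(X_test)
    return mean, var, var_noisy, gp.lml


def fitc_fit_predict(X, y, kernel: KernelSpec, inducing, X_test):
    """Convenience: fit FITC at fixed inducing inputs and predict."""
    gp = FITC(kernel, inducing).fit(X, y)
    mean, var, var_noisy = gp.predict(X_test)
    return mean, var, var_noisy, gp.lml


def poe_predict(X, y, kernel: KernelSpec, X_test, mode: str = "gpoe",
                B: int | None = None, partition=None, Z: float = 1.0):
    """Convenience: fit independent experts and aggregate with the given rule."""
    poe = PoEBaseline(kernel, B=B, partition=partition, mode=mode, Z=Z)
    poe.fit(X, y)
    return poe.predict(X_test)
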