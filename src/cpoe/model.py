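"""High-level estimator tying graph construction, inference and prediction."""

from __future__ import annotations

import numpy as np

from . import core, prediction
from .kernels import KernelSpec
from .partition import ExpertGraph, build_graph

__all__ = ["CPoEModel"]


class CPoEModel:
    """Correlated product-of-experts GP regression model.

    Parameters
    ----------
    kernel:
        Composite covariance function including the noise standard deviation.
    B:
        Target expert (partition) size; J = ceil(N / B) experts are built.
    C:
        Degree of correlation, 1 <= C <= J.  C = 1 gives independent experts,
        C = J recovers full GP (gamma = 1) or FITC (gamma < 1).
    gamma:
        Inducing-point sparsity in (0, 1]; each expert keeps
        floor(gamma * B_j) of its own inputs as local inducing inputs.
    seed:
        Drives the random inducing subsets and the ordering start.
    mode:
        Predecessor selection, "nearest" (default) or "consecutive".
    Z:
        Optional override of the weight exponent (default log(N) * C).
    jitter:
        Optional override of the relative jitter used in kernel-matrix
        factorizations (see :mod:`cpoe._linalg`).
    """

    def __init__(self, kernel: KernelSpec, B: int, C: int, gamma: float = 1.0,
                 seed: int | None = 0, mode: str = "nearest",
                 Z: float | None = None, jitter: float | None = None):
        self.kernel = kernel
        self.B = int(B)
        self.C = int(C)
        self.gamma = float(gamma)
        self.seed = seed
        self.mode = mode
        self.Z = Z
        self.jitter = jitter
        self.graph: ExpertGraph | None = None
        self.conds = None
        self.post = None
        self._X = None
        self._y = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CPoEModel":
        """Build the expert graph once and assemble the sparse posterior."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("X and y length mismatch")
        self.graph = build_graph(X, self.B, self.C, self.gamma,
                                 seed=self.seed, mode=self.mode)
        self._X, self._y = X, y
        self._recompute()
        return self

    def set_kernel(self, kernel: KernelSpec) -> "CPoEModel":
        """Swap hyperparameters and recompute inference on the fixed graph."""
        self.kernel = kernel
        if self.graph is not None:
            self._recompute()
        return self

    def _recompute(self) -> None:
        self.conds = core.compute_local_conditionals(self.kernel, self.graph,
                                                     self._X, jitter=self.jitter)
        self.post = core.posterior_state(self.conds, self.graph, self._y,
                                         self.kernel.noise_std)

    @property
    def lml(self) -> float:
        """Log marginal likelihood log q(y | theta) of the fitted model."""
        self._check_fitted()
        return self.post.lml

    def predict(self, X_test: np.ndarray, return_detail: bool = False):
        """Fused predictive mean, latent variance and noisy variance."""
        self._check_fitted()
        return prediction.predict(self.kernel, self.graph, self.conds,
                                  self.post, X_test, Z=self.Z,
                                  return_detail=return_detail)

    def _check_fitted(self) -> None:
        if self.post is None:
            raise RuntimeError("model is not fitted; call fit(X, y) first")
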