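"""Synthetic data: exact GP samples and the standard test geometries.

``make_two_se_benchmark`` draws from the sum of two squared-exponential
kernels with lengthscales a factor 10 apart, so that the response carries both
a smooth global trend and fine local structure.  ``make_fig8_toy`` builds a
small five-cluster planar dataset (J=5 experts of B=4 points, gamma=0.75 and
hence L=3 local inducing points each) for exercising the graph construction;
the cluster coordinates are synthetic, only the combinatorial structure is
prescribed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._linalg import jittered_cholesky
from .kernels import KernelSpec, SEard

__all__ = ["Dataset", "sample_inputs", "sample_gp",
           "make_two_se_benchmark", "make_fig8_toy"]

DENSE_SAMPLING_GUARD = 8192


@dataclass
class Dataset:
    """In-memory regression dataset with the latent function when known."""

    X: np.ndarray
    y: np.ndarray
    f: np.ndarray | None = None
    kernel: KernelSpec | None = None

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def D(self) -> int:
        return self.X.shape[1]


def sample_inputs(N: int, D: int, scheme: str = "uniform",
                  bounds: tuple = (0.0, 10.0),
                  seed: int | None = None) -> np.ndarray:
    """Reproducible input designs: uniform box samples or a sorted 1-D grid."""
    if N < 1 or D < 1:
        raise ValueError("N and D must be >= 1")
    lo, hi = map(float, bounds)
    if not hi > lo:
        raise ValueError("bounds must satisfy hi > lo")
    if scheme == "uniform":
        rng = np.random.default_rng(seed)
        return rng.uniform(lo, hi, size=(N, D))
    if scheme == "grid":
        if D == 1:
            return np.linspace(lo, hi, N)[:, None]
        side = int(np.ceil(N ** (1.0 / D)))
        axes = [np.linspace(lo, hi, side)] * D
        mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, D)
        return mesh[:N]
    raise ValueError(f"unknown input scheme {scheme!r}")


def sample_gp(kernel: KernelSpec, X: np.ndarray, noise_std: float | None = None,
              seed: int | None = None, guard: int = DENSE_SAMPLING_GUARD):
    """Exact dense draw f ~ N(0, K_XX) and noisy responses y = f + eps."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] > guard:
        raise ValueError(f"N={X.shape[0]} exceeds the dense sampling guard {guard}")
    if noise_std is None:
        noise_std = kernel.noise_std
    rng = np.random.default_rng(seed)
    L = jittered_cholesky(kernel(X, X))
    f = L @ rng.standard_normal(X.shape[0])
    y = f + noise_std * rng.standard_normal(X.shape[0]) if noise_std > 0 else f.copy()
    return f, y


def sample_gp_conditional(kernel: KernelSpec, X_train: np.ndarray,
                          f_train: np.ndarray, X_test: np.ndarray,
                          noise_std: float | None = None,
                          seed: int | None = None):
    """Held-out draws f* | f_train at each test point, plus noisy responses.

    Each test value is drawn from its *univariate* conditional given the
    training latents, independently across test points: the marginals are
    exact, so pointwise statements (coverage, RMSE against the truth) are
    unbiased, while joint statements across test points are not supported.
    Scales to many test points without a dense test-test covariance.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    f_train = np.asarray(f_train, dtype=float).ravel()
    if noise_std is None:
        noise_std = kernel.noise_std
    rng = np.random.default_rng(seed)
    L = jittered_cholesky(kernel(X_train, X_train))
    K_ts = kernel(X_train, X_test)                      # (N, Nt)
    from ._linalg import chol_solve
    W = chol_solve(L, K_ts)
    mean = W.T @ f_train
    var = np.maximum(kernel.diag(X_test) - np.sum(K_ts * W, axis=0), 0.0)
    f_test = mean + np.sqrt(var) * rng.standard_normal(X_test.shape[0])
    y_test = f_test + noise_std * rng.standard_normal(X_test.shape[0])
    return f_test, y_test


def make_two_se_benchmark(N: int = 1024, D: int = 2, seed: int = 0,
                          ell_short: float = 0.5, ell_long: float = 5.0,
                          variance: float = 1.0, noise_std: float = 0.1,
                          bounds: tuple = (0.0, 10.0)) -> Dataset:
    """GP data from SE(ell_long) + SE(ell_short): global plus local patterns."""
    kernel = KernelSpec(
        terms=(SEard(lengthscales=np.full(D, ell_long), variance=variance),
               SEard(lengthscales=np.full(D, ell_short), variance=variance)),
        noise_std=noise_std, input_dim=D)
    X = sample_inputs(N, D, "uniform", bounds, seed=seed)
    f, y = sample_gp(kernel, X, seed=seed + 1)
    return Dataset(X=X, y=y, f=f, kernel=kernel)


def make_fig8_toy(seed: int = 0) -> tuple[Dataset, dict]:
    """Five well-separated planar clusters of four points each.

    Returns the dataset together with the graph settings
    ``{"B": 4, "gamma": 0.75}`` under which each expert keeps L = 3 local
    inducing points.
    """
    rng = np.random.default_rng(seed)
    centers = np.array([[0.0, 0.0], [3.0, 1.0], [6.0, 0.0],
                        [9.0, 1.0], [12.0, 0.0]])
    X = np.vstack([c + rng.uniform(-0.6, 0.6, size=(4, 2)) for c in centers])
    kernel = KernelSpec(terms=(SEard(lengthscales=np.array([3.0, 3.0]),
                                     variance=1.0),),
                        noise_std=0.1, input_dim=2)
    f, y = sample_gp(kernel, X, seed=seed + 1)
    return Dataset(X=X, y=y, f=f, kernel=kernel), {"B": 4, "gamma": 0.75}
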