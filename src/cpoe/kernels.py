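"""Composite positive-definite covariance functions and their hyperparameters.

A :class:`KernelSpec` is an ordered sum of base terms (squared-exponential
with per-dimension lengthscales, periodic, linear, arcsine "infinite MLP",
spectral mixture) plus an observation-noise standard deviation ``noise_std``.
All parameters are strictly positive; the optimizer works on the
log-transformed vector produced by :func:`pack_theta`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "KernelSpec",
    "SEard",
    "Periodic",
    "Linear",
    "MLPArcsine",
    "SpectralMixture",
    "build_kernel",
    "spec_to_config",
    "eval_kernel",
    "n_hyperparameters",
    "pack_theta",
    "unpack_theta",
]


def _check_positive(name: str, value: np.ndarray | float) -> None:
    arr = np.asarray(value, dtype=float)
    if arr.size == 0 or not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"kernel parameter {name!r} must be strictly positive "
                         f"and finite, got {value!r}")


def _sqdist(X1: np.ndarray, X2: np.ndarray, scale: np.ndarray | None = None) -> np.ndarray:
    """Pairwise squared Euclidean distances, optionally per-dimension scaled."""
    if scale is not None:
        X1 = X1 / scale
        X2 = X2 / scale
    n1 = np.sum(X1 ** 2, axis=1)[:, None]
    n2 = np.sum(X2 ** 2, axis=1)[None, :]
    d2 = n1 + n2 - 2.0 * X1 @ X2.T
    np.maximum(d2, 0.0, out=d2)
    return d2


@dataclass(frozen=True)
class SEard:
    """Squared exponential with individual lengthscales per input dimension.

    k(x, x') = variance * exp(-1/2 * sum_d (x_d - x'_d)^2 / lengthscales_d^2)
    """

    lengthscales: np.ndarray
    variance: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "lengthscales",
                           np.atleast_1d(np.asarray(self.lengthscales, dtype=float)))
        _check_positive("lengthscales", self.lengthscales)
        _check_positive("variance", self.variance)

    @property
    def n_params(self) -> int:
        return self.lengthscales.size + 1

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([self.lengthscales, [self.variance]])

    def with_theta(self, theta: np.ndarray) -> "SEard":
        return SEard(lengthscales=theta[:-1].copy(), variance=float(theta[-1]))

    def __call__(self, X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
        return self.variance * np.exp(-0.5 * _sqdist(X1, X2, self.lengthscales))


@dataclass(frozen=True)
class Periodic:
    """Standard periodic kernel acting on one input dimension (default the first).

    k(t, t') = variance * exp(-2 sin^2(pi |t - t'| / period) / lengthscale^2)
    """

    variance: float
    lengthscale: float
    period: float
    dim: int = 0

    def __post_init__(self):
        _check_positive("variance", self.variance)
        _check_positive("lengthscale", self.lengthscale)
        _check_positive("period", self.period)

    n_params = 3

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.variance, self.lengthscale, self.period])

    def with_theta(self, theta: np.ndarray) -> "Periodic":
        return replace(self, variance=float(theta[0]), lengthscale=float(theta[1]),
                       period=float(theta[2]))

    def __call__(self, X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
        tau = X1[:, self.dim][:, None] - X2[:, self.dim][None, :]
        s = np.sin(np.pi * np.abs(tau) / self.period) / self.lengthscale
        return self.variance * np.exp(-2.0 * s ** 2)


@dataclass(frozen=True)
class Linear:
    """Dot-product kernel k(x, x') = variance * x . x'."""

    variance: float

    def __post_init__(self):
        _check_positive("variance", self.variance)

    n_params = 1

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.variance])

    def with_theta(self, theta: np.ndarray) -> "Linear":
        return Linear(variance=float(theta[0]))

    def __call__(self, X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
        return self.variance * (X1 @ X2.T)


@dataclass(frozen=True)
class MLPArcsine:
    """Arcsine kernel of an infinitely wide one-hidden-layer network.

    With augmented input x~ = [1, x] and prior covariance
    Sigma = diag(bias_var, weight_var * I),

        k(x, x') = variance * (2/pi) * asin( 2 x~' Sigma x~'
                    / sqrt((1 + 2 x~' Sigma x~)(1 + 2 x~'' Sigma x~'')) ).
    """

    variance: float
    weight_var: float = 1.0
    bias_var: float = 1.0

    def __post_init__(self):
        _check_positive("variance", self.variance)
        _check_positive("weight_var", self.weight_var)
        _check_positive("bias_var", self.bias_var)

    n_params = 3

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.variance, self.weight_var, self.bias_var])

    def with_theta(self, theta: np.ndarray) -> "MLPArcsine":
        return MLPArcsine(variance=float(theta[0]), weight_var=float(theta[1]),
                          bias_var=float(theta[2]))

    def __call__(self, X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
        inner = 2.0 * (self.bias_var + self.weight_var * (X1 @ X2.T))
        d1 = 1.0 + 2.0 * (self.bias_var + self.weight_var * np.sum(X1 ** 2, axis=1))
        d2 = 1.0 + 2.0 * (self.bias_var + self.weight_var * np.sum(X2 ** 2, axis=1))
        arg = inner / np.sqrt(d1[:, None] * d2[None, :])
        # clip guards round-off at coincident inputs where arg -> 1
        return self.variance * (2.0 / np.pi) * np.arcsin(np.clip(arg, -1.0, 1.0))


@dataclass(frozen=True)
class SpectralMixture:
    """Spectral mixture: weighted cosine-modulated Gaussians in the frequency domain.

    k(tau) = sum_q weights_q * prod_d exp(-2 pi^2 tau_d^2 scales_qd) * cos(2 pi means_qd tau_d)

    ``means`` are spectral frequencies and ``scales`` the per-dimension
    variances of the Gaussian spectral components; both are (Q, D).
    """

    weights: np.ndarray
    means: np.ndarray
    scales: np.ndarray

    def __post_init__(self):
        w = np.atleast_1d(np.asarray(self.weights, dtype=float))
        m = np.atleast_2d(np.asarray(self.means, dtype=float))
        s = np.atleast_2d(np.asarray(self.scales, dtype=float))
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "scales", s)
        _check_positive("weights", w)
        _check_positive("means", m)
        _check_positive("scales", s)
        if m.shape != s.shape or m.shape[0] != w.size:
            raise ValueError("spectral mixture shapes inconsistent: "
                             f"weights {w.shape}, means {m.shape}, scales {s.shape}")

    @property
    def n_params(self) -> int:
        return self.weights.size + self.means.size + self.scales.size

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([self.weights, self.means.ravel(), self.scales.ravel()])

    def with_theta(self, theta: np.ndarray) -> "SpectralMixture":
        q, d = self.means.shape
        w = theta[:q]
        m = theta[q:q + q * d].reshape(q, d)
        s = theta[q + q * d:].reshape(q, d)
        return SpectralMixture(weights=w.copy(), means=m, scales=s)

    def __call__(self, X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
        tau = X1[:, None, :] - X2[None, :, :]          # (n1, n2, D)
        out = np.zeros((X1.shape[0], X2.shape[0]))
        for q in range(self.weights.size):
            envelope = np.exp(-2.0 * np.pi ** 2 * np.sum(tau ** 2 * self.scales[q], axis=-1))
            carrier = np.prod(np.cos(2.0 * np.pi * tau * self.means[q]), axis=-1)
            out += self.weights[q] * envelope * carrier
        return out


_TERM_TYPES = {
    "se_ard": SEard,
    "periodic": Periodic,
    "linear": Linear,
    "mlp_arcsine": MLPArcsine,
    "spectral_mixture": SpectralMixture,
}


@dataclass(frozen=True)
class KernelSpec:
    """Sum-of-terms covariance function with observation noise ``noise_std``."""

    terms: tuple
    noise_std: float
    input_dim: int

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        if not self.terms:
            raise ValueError("kernel needs at least one term")
        _check_positive("noise_std", self.noise_std)
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        for t in self.terms:
            if isinstance(t, SEard) and t.lengthscales.size != self.input_dim:
                raise ValueError(
                    f"se_ard has {t.lengthscales.size} lengthscales "
                    f"but input_dim={self.input_dim}")
            if isinstance(t, SpectralMixture) and t.means.shape[1] != self.input_dim:
                raise ValueError("spectral_mixture frequency dimension mismatch")

    def __call__(self, X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
        return eval_kernel(self, X1, X2)

    def diag(self, X: np.ndarray) -> np.ndarray:
        """Pointwise prior variances k(x, x) without forming the full matrix."""
        X = _as_2d(X, self.input_dim)
        out = np.zeros(X.shape[0])
        for t in self.terms:
            if isinstance(t, SEard):
                out += t.variance
            elif isinstance(t, Periodic):
                out += t.variance
            elif isinstance(t, SpectralMixture):
                out += np.sum(t.weights)
            elif isinstance(t, Linear):
                out += t.variance * np.sum(X ** 2, axis=1)
            elif isinstance(t, MLPArcsine):
                s = t.bias_var + t.weight_var * np.sum(X ** 2, axis=1)
                out += t.variance * (2.0 / np.pi) * np.arcsin(2.0 * s / (1.0 + 2.0 * s))
            else:  # pragma: no cover - future terms
                out += np.array([t(X[i:i + 1], X[i:i + 1])[0, 0]
                                 for i in range(X.shape[0])])
        return out

    @property
    def n_hyperparameters(self) -> int:
        return n_hyperparameters(self)


def _as_2d(X: np.ndarray, D: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None] if D == 1 else X[None, :]
    if X.ndim != 2 or X.shape[1] != D:
        raise ValueError(f"expected inputs with {D} columns, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in kernel inputs")
    return X


def build_kernel(config: dict) -> KernelSpec:
    """Build a validated :class:`KernelSpec` from a plain config mapping.

    ``config`` holds ``input_dim``, ``noise_std`` and a ``terms`` list of
    ``{"type": name, **params}`` mappings; term order is preserved.
    """
    D = int(config["input_dim"])
    noise = float(config["noise_std"])
    terms = []
    for block in config["terms"]:
        block = dict(block)
        name = block.pop("type")
        if name not in _TERM_TYPES:
            raise ValueError(f"unknown kernel term type {name!r}; "
                             f"known: {sorted(_TERM_TYPES)}")
        cls = _TERM_TYPES[name]
        if name == "se_ard":
            ls = block.get("lengthscales")
            if ls is None:
                ls = np.full(D, float(block.pop("lengthscale", 1.0)))
            else:
                block.pop("lengthscales")
                ls = np.atleast_1d(np.asarray(ls, dtype=float))
            terms.append(cls(lengthscales=ls, **block))
        else:
            terms.append(cls(**block))
    return KernelSpec(terms=tuple(terms), noise_std=noise, input_dim=D)


def spec_to_config(spec: KernelSpec) -> dict:
    """Inverse of :func:`build_kernel`: a plain JSON/YAML-serializable mapping."""
    terms = []
    for t in spec.terms:
        if isinstance(t, SEard):
            terms.append({"type": "se_ard",
                          "lengthscales": t.lengthscales.tolist(),
                          "variance": t.variance})
        elif isinstance(t, Periodic):
            terms.append({"type": "periodic", "variance": t.variance,
                          "lengthscale": t.lengthscale, "period": t.period,
                          "dim": t.dim})
        elif isinstance(t, Linear):
            terms.append({"type": "linear", "variance": t.variance})
        elif isinstance(t, MLPArcsine):
            terms.append({"type": "mlp_arcsine", "variance": t.variance,
                          "weight_var": t.weight_var, "bias_var": t.bias_var})
        elif isinstance(t, SpectralMixture):
            terms.append({"type": "spectral_mixture",
                          "weights": t.weights.tolist(),
                          "means": t.means.tolist(),
                          "scales": t.scales.tolist()})
        else:  # pragma: no cover
            raise TypeError(f"cannot serialize kernel term {type(t).__name__}")
    return {"input_dim": spec.input_dim, "noise_std": spec.noise_std,
            "terms": terms}


def eval_kernel(spec: KernelSpec, X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Evaluate the composite kernel matrix K[i, j] = k(X1_i, X2_j)."""
    X1 = _as_2d(X1, spec.input_dim)
    X2 = _as_2d(X2, spec.input_dim)
    K = np.zeros((X1.shape[0], X2.shape[0]))
    for t in spec.terms:
        K += t(X1, X2)
    return K


def n_hyperparameters(spec: KernelSpec) -> int:
    """Number of trainable parameters: term parameters plus the noise std."""
    return sum(t.n_params for t in spec.terms) + 1


def pack_theta(spec: KernelSpec) -> np.ndarray:
    """Map positive hyperparameters to the unconstrained log-space vector."""
    theta = np.concatenate([t.theta for t in spec.terms] + [[spec.noise_std]])
    return np.log(theta)


def unpack_theta(spec: KernelSpec, packed: np.ndarray) -> KernelSpec:
    """Inverse of :func:`pack_theta`; positivity enforced by the exp map."""
    packed = np.asarray(packed, dtype=float)
    if packed.size != n_hyperparameters(spec):
        raise ValueError(f"expected {n_hyperparameters(spec)} packed parameters, "
                         f"got {packed.size}")
    theta = np.exp(packed)
    terms = []
    k = 0
    for t in spec.terms:
        terms.append(t.with_theta(theta[k:k + t.n_params]))
        k += t.n_params
    return KernelSpec(terms=tuple(terms), noise_std=float(theta[-1]),
                      input_dim=spec.input_dim)
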