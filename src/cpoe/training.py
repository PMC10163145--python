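"""Deterministic hyperparameter estimation by marginal-likelihood maximization.

The objective is the analytic log marginal likelihood of the correlated
product of experts, optionally plus log-normal log-priors on the positive
hyperparameters (MAP).  Optimization runs on the log-transformed parameter
vector with L-BFGS-B and finite-difference gradients; the expert graph
(partition, ordering, predecessor sets) is built once from the initial inputs
and held fixed, so the objective is a smooth function of the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .kernels import KernelSpec, SEard, n_hyperparameters, pack_theta, unpack_theta
from .model import CPoEModel

__all__ = ["FitConfig", "lognormal_logprior", "fit_hyperparameters",
           "default_se_kernel"]


@dataclass
class FitConfig:
    """Optimizer settings for LML or MAP hyperparameter estimation."""

    objective: str = "lml"            # "lml" or "map"
    maxiter: int = 200
    tol: float = 1e-8
    restarts: int = 1
    seed: int = 0
    restart_sd: float = 0.3           # log-space jitter of restart initializations
    prior_locations: np.ndarray | None = None   # log-space means m_i
    prior_scales: np.ndarray | None = None      # log-space std devs s_i > 0
    jitter: float = 1e-6   # moderate jitter keeps the objective smooth

    def __post_init__(self):
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.objective not in ("lml", "map"):
            raise ValueError("objective must be 'lml' or 'map'")
        if self.objective == "map":
            if self.prior_locations is None or self.prior_scales is None:
                raise ValueError("map objective needs prior locations and scales")
            if np.any(np.asarray(self.prior_scales) <= 0):
                raise ValueError("prior scales must be positive")


def lognormal_logprior(theta: np.ndarray, locations: np.ndarray,
                       scales: np.ndarray) -> float:
    """Sum of log-normal log densities sum_i log LogN(theta_i; m_i, s_i)."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("log-normal prior requires positive parameters")
    m = np.asarray(locations, dtype=float)
    s = np.asarray(scales, dtype=float)
    z = (np.log(theta) - m) / s
    return float(np.sum(-np.log(theta * s * np.sqrt(2.0 * np.pi)) - 0.5 * z ** 2))


def default_se_kernel(X: np.ndarray, y: np.ndarray) -> KernelSpec:
    """Moment-based starting kernel: lengthscales = per-dimension input std,
    signal std = response std, noise std = 0.1 * signal std."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] > X.shape[0]:
        X = X.T
    y = np.asarray(y, dtype=float).ravel()
    ls = np.std(X, axis=0)
    ls[ls == 0] = 1.0
    sf = float(np.std(y)) or 1.0
    return KernelSpec(terms=(SEard(lengthscales=ls, variance=sf ** 2),),
                      noise_std=0.1 * sf, input_dim=X.shape[1])


def fit_hyperparameters(X: np.ndarray, y: np.ndarray, kernel0: KernelSpec,
                        graph_settings: dict, config: FitConfig | None = None):
    """Maximize the (penalized) LML over log hyperparameters.

    ``graph_settings`` carries B, C and optionally gamma / mode / seed / Z for
    the expert graph, which is constructed once and reused across objective
    evaluations.  Returns ``(model, trace)`` where ``trace`` is the list of
    (evaluation, objective, best_so_far) rows across all restarts and the
    model carries the best parameters found.
    """
    config = config or FitConfig()
    model = CPoEModel(kernel0, jitter=config.jitter, **graph_settings)
    model.fit(X, y)

    n_par = n_hyperparameters(kernel0)
    if config.objective == "map":
        locs = np.asarray(config.prior_locations, dtype=float)
        scls = np.asarray(config.prior_scales, dtype=float)
        if locs.size != n_par or scls.size != n_par:
            raise ValueError(f"priors must cover all {n_par} parameters")

    trace: list[tuple[int, float, float]] = []
    state = {"best": -np.inf, "evals": 0}

    def objective(packed: np.ndarray) -> float:
        try:
            with np.errstate(over="raise"):
                spec = unpack_theta(kernel0, packed)
            model.set_kernel(spec)
            val = model.lml
            if config.objective == "map":
                val += lognormal_logprior(np.exp(packed), locs, scls)
        except (np.linalg.LinAlgError, FloatingPointError, ValueError,
                OverflowError):
            val = -np.inf
        state["evals"] += 1
        if np.isfinite(val) and val > state["best"]:
            state["best"] = val
        trace.append((state["evals"], float(val), float(state["best"])))
        return -val if np.isfinite(val) else 1e100

    x0 = pack_theta(kernel0)
    if not np.isfinite(objective(x0)):
        raise ValueError("objective not finite at the initial point")
    rng = np.random.default_rng(config.seed)
    best_x, best_val = None, -np.inf
    for r in range(config.restarts):
        start = x0 if r == 0 else x0 + rng.normal(0.0, config.restart_sd, x0.size)
        # box in log space: e^-12 .. e^12 covers any reasonable scale
        res = optimize.minimize(objective, start, method="L-BFGS-B",
                                bounds=[(-12.0, 12.0)] * x0.size,
                                options={"maxiter": config.maxiter,
                                         "ftol": config.tol})
        if np.isfinite(res.fun) and -res.fun > best_val:
            best_val, best_x = -res.fun, res.x
    if best_x is None:
        raise RuntimeError("all restarts failed to reach a finite objective")
    model.set_kernel(unpack_theta(kernel0, best_x))
    return model, trace
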