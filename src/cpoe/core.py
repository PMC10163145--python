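"""Sparse-precision inference for the correlated product of experts.

Per expert j the model uses two Gaussian conditionals derived from the GP
prior:

* prior transition  p(a_j | a_pi(j))  = N(F_j a_pi(j), Q_j) with
  F_j = K_{A_j A_pi} K_{A_pi A_pi}^-1 and Q_j the matching Schur complement
  (F_1 empty, Q_1 = K_{A_1 A_1});
* projection        p(f_j | a_psi(j)) = N(H_j a_psi(j), Vbar_j) with
  H_j = K_{X_j A_psi} K_{A_psi A_psi}^-1 and diagonal Vbar_j.

Stacking the transitions gives a unit-lower-triangular sparse F and the prior
precision S = F' Q^-1 F over all M inducing outputs; adding the projection
precision T = H' V^-1 H (V = Vbar + sigma_n^2 I) yields the sparse posterior
precision Lambda = S + T with natural parameters eta = H' V^-1 y.  The log
marginal likelihood log N(y | 0, H S^-1 H' + V) is evaluated without forming
the dense N x N matrix via

    log|P| = log|Lambda| - log|S| + log|V|,
    y' P^-1 y = y' V^-1 y - eta' mu.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from ._linalg import chol_logdet, chol_solve, jittered_cholesky
from .kernels import KernelSpec
from .partition import ExpertGraph

__all__ = [
    "LocalConditionals",
    "SparsePosterior",
    "compute_local_conditionals",
    "assemble_F_H",
    "prior_precision",
    "posterior_state",
    "log_marginal_likelihood",
]


@dataclass
class LocalConditionals:
    """Per-expert conditional blocks plus cached factors reused at prediction."""

    H: list            # J matrices (B_j, L * |psi(j)|)
    Vbar: list         # J vectors (B_j,), elementwise >= 0
    F: list            # J matrices (L_j, L * |pi(j)|); F[0] has 0 columns
    Q: list            # J SPD matrices (L_j, L_j)
    chol_Q: list       # lower Cholesky factors of Q_j
    logdet_Q: np.ndarray
    A_psi: list        # stacked inducing inputs over psi(j)
    chol_K_psi: list   # lower Cholesky factors of K_{A_psi A_psi}

    @property
    def logdet_S(self) -> float:
        """log|S| = -sum_j log|Q_j| because F is unit lower triangular."""
        return -float(np.sum(self.logdet_Q))


def compute_local_conditionals(kernel: KernelSpec, graph: ExpertGraph,
                               X: np.ndarray,
                               jitter: float | None = None) -> LocalConditionals:
    """Evaluate H_j, Vbar_j, F_j, Q_j for every expert of the graph.

    ``jitter`` overrides the default relative jitter of the kernel-matrix
    Cholesky factorizations (larger values give a smoother but slightly
    biased marginal likelihood, useful during hyperparameter optimization).
    """
    X = np.asarray(X, dtype=float)
    H, Vbar, F, Q, cholQ, A_psis, chol_psis = [], [], [], [], [], [], []
    logdetQ = np.zeros(graph.J)
    psi_cache: dict[tuple, tuple] = {}

    for j in range(graph.J):
        psi = graph.psi[j]
        key = tuple(psi)
        if key not in psi_cache:
            A_psi = X[np.concatenate([graph.inducing_idx[k] for k in psi])]
            psi_cache[key] = (A_psi,
                              jittered_cholesky(kernel(A_psi, A_psi), jitter))
        A_psi, L_psi = psi_cache[key]
        X_j = X[graph.partition[j]]
        K_x_psi = kernel(X_j, A_psi)
        H_j = chol_solve(L_psi, K_x_psi.T).T
        vbar = kernel.diag(X_j) - np.sum(K_x_psi * H_j, axis=1)
        Vbar.append(np.maximum(vbar, 0.0))
        H.append(H_j)
        A_psis.append(A_psi)
        chol_psis.append(L_psi)

        A_j = X[graph.inducing_idx[j]]
        K_jj = kernel(A_j, A_j)
        pi = graph.pi[j]
        if pi.size == 0:
            F_j = np.zeros((A_j.shape[0], 0))
            Q_j = K_jj
        else:
            A_pi = X[np.concatenate([graph.inducing_idx[k] for k in pi])]
            L_pi = jittered_cholesky(kernel(A_pi, A_pi), jitter)
            K_j_pi = kernel(A_j, A_pi)
            F_j = chol_solve(L_pi, K_j_pi.T).T
            Q_j = K_jj - F_j @ K_j_pi.T
            Q_j = 0.5 * (Q_j + Q_j.T)
        F.append(F_j)
        Q.append(Q_j)
        # jitter scaled by the parent kernel diagonal: the Schur complement's
        # own diagonal underestimates its roundoff when C or the lengthscales
        # are large
        Lq = jittered_cholesky(Q_j, jitter,
                               scale=float(np.mean(np.diag(K_jj))))
        cholQ.append(Lq)
        logdetQ[j] = chol_logdet(Lq)

    return LocalConditionals(H=H, Vbar=Vbar, F=F, Q=Q, chol_Q=cholQ,
                             logdet_Q=logdetQ, A_psi=A_psis, chol_K_psi=chol_psis)


def _blocks_to_coo(entries, shape) -> sparse.csr_matrix:
    rows, cols, vals = [], [], []
    for r0, c0, block in entries:
        if block.size == 0:
            continue
        ri, ci = np.meshgrid(np.arange(block.shape[0]) + r0,
                             np.arange(block.shape[1]) + c0, indexing="ij")
        rows.append(ri.ravel())
        cols.append(ci.ravel())
        vals.append(block.ravel())
    if not rows:
        return sparse.csr_matrix(shape)
    return sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=shape).tocsr()


def assemble_F_H(conds: LocalConditionals, graph: ExpertGraph):
    """Stack the per-expert blocks into the sparse transition and projection.

    F carries identity blocks on its block diagonal and -F_j^i at block column
    pi^i(j), so (F a)_j = a_j - F_j a_pi(j); H carries H_j^i at block row j,
    block column psi^i(j).  Rows of H follow the permuted (stacked-partition)
    data order.
    """
    off = graph.offsets
    M = graph.M
    L = graph.L

    f_entries = []
    for j in range(graph.J):
        f_entries.append((off[j], off[j], np.eye(L[j])))
        c = 0
        for k in graph.pi[j]:
            f_entries.append((off[j], off[k], -conds.F[j][:, c:c + L[k]]))
            c += L[k]
    F = _blocks_to_coo(f_entries, (M, M))

    row_off = np.concatenate([[0], np.cumsum(graph.sizes)])
    N = int(graph.sizes.sum())
    h_entries = []
    for j in range(graph.J):
        c = 0
        for k in graph.psi[j]:
            h_entries.append((row_off[j], off[k], conds.H[j][:, c:c + L[k]]))
            c += L[k]
    H = _blocks_to_coo(h_entries, (N, M))
    return F, H


def prior_precision(F: sparse.spmatrix, conds: LocalConditionals,
                    graph: ExpertGraph) -> sparse.csr_matrix:
    """Prior precision S = F' Q^-1 F over the stacked inducing outputs."""
    Qinv_blocks = [chol_solve(Lq, np.eye(Lq.shape[0])) for Lq in conds.chol_Q]
    Qinv = sparse.block_diag(Qinv_blocks, format="csr")
    S = (F.T @ Qinv @ F).tocsr()
    S = 0.5 * (S + S.T)
    return S.tocsr()


@dataclass
class SparsePosterior:
    """Posterior state q(a | y) = N(mu, Lambda^-1) plus cached determinants."""

    S: sparse.csr_matrix
    T: sparse.csr_matrix
    Lambda: sparse.csr_matrix
    eta: np.ndarray
    mu: np.ndarray
    factor: object          # splu factorization of Lambda
    V: np.ndarray           # diagonal of Vbar + sigma_n^2 I, permuted order
    y: np.ndarray           # responses in permuted order
    perm: np.ndarray        # original data index of each permuted row
    logdet_S: float
    logdet_Lambda: float
    logdet_V: float
    lml: float

    @property
    def M(self) -> int:
        return self.mu.size

    def solve(self, B: np.ndarray) -> np.ndarray:
        """Solve Lambda x = B through the sparse factorization."""
        return self.factor.solve(np.asarray(B, dtype=float))


def _splu_logdet(lu) -> float:
    # Lambda is SPD so det > 0; the LU diagonal magnitudes carry |det|.
    return float(np.sum(np.log(np.abs(lu.U.diagonal()))))


def posterior_state(conds: LocalConditionals, graph: ExpertGraph,
                    y: np.ndarray, noise_std: float) -> SparsePosterior:
    """Assemble Lambda = S + T, solve Lambda mu = eta, and cache the LML."""
    if noise_std <= 0:
        raise ValueError("noise_std must be positive")
    y = np.asarray(y, dtype=float).ravel()
    perm = np.concatenate(graph.partition)
    y_p = y[perm]

    F, H = assemble_F_H(conds, graph)
    S = prior_precision(F, conds, graph)
    V = np.concatenate(conds.Vbar) + noise_std ** 2
    Vinv = 1.0 / V
    HtVi = H.T.multiply(Vinv)            # M x N, column-scaled
    T = (HtVi @ H).tocsr()
    T = 0.5 * (T + T.T)
    Lam = (S + T).tocsc()
    Lam = 0.5 * (Lam + Lam.T)
    factor = splu(Lam.tocsc())
    eta = np.asarray(HtVi @ y_p).ravel()
    mu = factor.solve(eta)

    logdet_S = conds.logdet_S
    logdet_Lam = _splu_logdet(factor)
    logdet_V = float(np.sum(np.log(V)))
    N = y_p.size
    quad = float(y_p @ (Vinv * y_p) - eta @ mu)
    logdet_P = logdet_Lam - logdet_S + logdet_V
    lml = -0.5 * (N * np.log(2.0 * np.pi) + logdet_P + quad)
    if not np.isfinite(lml):
        raise FloatingPointError("non-finite log marginal likelihood "
                                 "(conditioning problem in the sparse system)")

    return SparsePosterior(S=S, T=T, Lambda=Lam.tocsr(), eta=eta, mu=mu,
                           factor=factor, V=V, y=y_p, perm=perm,
                           logdet_S=logdet_S, logdet_Lambda=logdet_Lam,
                           logdet_V=logdet_V, lml=lml)


def log_marginal_likelihood(post: SparsePosterior) -> float:
    """log N(y | 0, H S^-1 H' + V) of the assembled model (cached)."""
    return post.lml
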