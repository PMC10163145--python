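"""Ordered data partition, local inducing points and the expert dependency graph.

The data are split into J spatially coherent blocks ("experts") with a
KD-tree-style recursive median split, ordered by a greedy nearest-center walk,
and each expert receives a random subset of its own inputs as local inducing
points (L_j = floor(gamma * B_j)).  The directed graph between experts is
encoded by predecessor sets pi_C(j) (the C-1 closest earlier experts, or the
C-1 immediately preceding ones in consecutive mode) and correlation sets
psi_C(j) = pi_C(j) + {j} (the first C experts share psi = {1..C}).

All expert indices below are 0-based positions in the ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpertGraph",
    "kdtree_partition",
    "select_local_inducing",
    "order_partitions",
    "build_predecessor_sets",
    "build_correlation_sets",
    "build_graph",
]


def kdtree_partition(X: np.ndarray, B: int, seed: int | None = None) -> list[np.ndarray]:
    """Split N points into J = ceil(N/B) spatially coherent index sets.

    Recursive median-style split along the dimension of largest spread; leaf
    sizes differ by at most one (each is floor(N/J) or ceil(N/J)).  The split
    is deterministic: ties in a coordinate are broken by original index, so
    ``seed`` is accepted only for interface symmetry.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite inputs")
    N = X.shape[0]
    if not 1 <= B <= N:
        raise ValueError(f"batch size B={B} must satisfy 1 <= B <= N={N}")
    J = int(np.ceil(N / B))
    base, extra = divmod(N, J)
    sizes = [base + 1] * extra + [base] * (J - extra)

    def split(idx: np.ndarray, sizes: list[int]) -> list[np.ndarray]:
        if len(sizes) == 1:
            return [np.sort(idx)]
        half = (len(sizes) + 1) // 2
        n_left = sum(sizes[:half])
        spread = X[idx].max(axis=0) - X[idx].min(axis=0)
        dim = int(np.argmax(spread))
        order = idx[np.argsort(X[idx, dim], kind="stable")]
        return (split(order[:n_left], sizes[:half])
                + split(order[n_left:], sizes[half:]))

    return split(np.arange(N), sizes)


def select_local_inducing(partition: np.ndarray, gamma: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Random subset of L = floor(gamma * B_j) indices from one partition.

    gamma = 1 returns the whole partition (inducing inputs equal the expert's
    own inputs).  Returned indices are sorted.
    """
    if not 0.0 < gamma <= 1.0:
        raise ValueError("gamma must lie in (0, 1]")
    partition = np.asarray(partition)
    B_j = partition.size
    L_j = int(np.floor(gamma * B_j))
    if L_j == 0:
        raise ValueError(f"floor(gamma * B_j) = 0 for B_j={B_j}, gamma={gamma}")
    if L_j == B_j:
        return np.sort(partition)
    pick = rng.choice(B_j, size=L_j, replace=False)
    return np.sort(partition[pick])


def order_partitions(sets: list[np.ndarray], X: np.ndarray, gamma: float,
                     seed: int | None = None):
    """Order the partitions by a greedy nearest-center walk.

    A seed-chosen random start partition is greedily extended by the unvisited
    partition whose inducing-point center is closest (Euclidean) to the center
    of the most recently added partition; distance ties take the smallest
    original partition index.  Returns ``(order, inducing_idx, centers)`` where
    ``inducing_idx`` holds global data indices and both lists follow the order.
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    J = len(sets)
    if any(len(s) == 0 for s in sets):
        raise ValueError("empty partition")
    inducing = [select_local_inducing(s, gamma, rng) for s in sets]
    centers = np.array([X[ind].mean(axis=0) for ind in inducing])

    start = int(rng.integers(J))
    order = [start]
    remaining = [j for j in range(J) if j != start]
    while remaining:
        last = centers[order[-1]]
        d = np.linalg.norm(centers[remaining] - last, axis=1)
        order.append(remaining.pop(int(np.argmin(d))))
    order = np.array(order)
    return order, [inducing[j] for j in order], centers[order]


def build_predecessor_sets(centers: np.ndarray, C: int,
                           mode: str = "nearest") -> list[np.ndarray]:
    """Predecessor sets pi_C(j) of size min(j, C-1) over ordered experts.

    ``nearest`` ranks the earlier experts once by center distance to expert j,
    making pi_{C+1}(j) a superset of pi_C(j) by construction; ``consecutive``
    takes the immediately preceding experts.  Ties take the smaller index.
    """
    J = centers.shape[0]
    if not 1 <= C <= J:
        raise ValueError(f"C={C} out of range [1, {J}]")
    pi: list[np.ndarray] = []
    for j in range(J):
        take = min(j, C - 1)
        if take == 0:
            pi.append(np.array([], dtype=int))
        elif mode == "consecutive":
            pi.append(np.arange(j - take, j))
        elif mode == "nearest":
            d = np.linalg.norm(centers[:j] - centers[j], axis=1)
            ranked = np.argsort(d, kind="stable")
            pi.append(np.sort(ranked[:take]))
        else:
            raise ValueError(f"unknown predecessor mode {mode!r}")
    return pi


def build_correlation_sets(pi: list[np.ndarray], C: int, J: int) -> list[np.ndarray]:
    """Correlation sets psi_C(j): pi_C(j) + {j} for j >= C, else {0, ..., C-1}."""
    psi = []
    for j in range(J):
        if j < C:  # the first C experts share the exact corner block
            psi.append(np.arange(min(C, J)))
        else:
            psi.append(np.sort(np.append(pi[j], j)))
    return psi


@dataclass
class ExpertGraph:
    """Ordered partition plus the directed dependency structure between experts.

    ``partition``/``inducing_idx`` store global data indices per ordered
    expert; ``pi``/``psi`` store 0-based expert positions in the ordering.
    """

    J: int
    B: int
    C: int
    gamma: float
    consecutive: bool
    partition: list        # J arrays of data indices (ordering applied)
    inducing_idx: list     # J arrays of data indices, subsets of partition
    centers: np.ndarray    # (J, D) inducing-input means
    pi: list               # predecessor sets
    psi: list              # correlation sets
    order: np.ndarray      # original partition index at each position

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(p) for p in self.partition])

    @property
    def L(self) -> np.ndarray:
        return np.array([len(a) for a in self.inducing_idx])

    @property
    def M(self) -> int:
        return int(self.L.sum())

    @property
    def offsets(self) -> np.ndarray:
        """Start offset of each expert's inducing block in the stacked a-vector."""
        return np.concatenate([[0], np.cumsum(self.L)])

    def block_slice(self, j: int) -> slice:
        off = self.offsets
        return slice(off[j], off[j + 1])

    def block_indices(self, experts) -> np.ndarray:
        """Stacked a-vector indices of a set of experts (ascending expert order)."""
        off = self.offsets
        return np.concatenate([np.arange(off[j], off[j + 1]) for j in experts]) \
            if len(experts) else np.array([], dtype=int)

    def to_dict(self) -> dict:
        return {
            "J": self.J, "B": self.B, "C": self.C, "gamma": self.gamma,
            "consecutive": self.consecutive,
            "order": self.order.tolist(),
            "sizes": self.sizes.tolist(),
            "n_inducing": self.L.tolist(),
            "partition": [p.tolist() for p in self.partition],
            "inducing_idx": [a.tolist() for a in self.inducing_idx],
            "pi": [p.tolist() for p in self.pi],
            "psi": [p.tolist() for p in self.psi],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def build_graph(X: np.ndarray, B: int, C: int, gamma: float = 1.0,
                seed: int | None = None, mode: str = "nearest") -> ExpertGraph:
    """Partition, order and wire the experts for a dataset in one call.

    A single integer ``seed`` drives all random choices (inducing subsets in
    original partition order, then the starting partition of the ordering).
    """
    X = np.asarray(X, dtype=float)
    sets = kdtree_partition(X, B, seed)
    order, inducing, centers = order_partitions(sets, X, gamma, seed)
    J = len(sets)
    if not 1 <= C <= J:
        raise ValueError(f"C={C} out of range [1, {J}]")
    pi = build_predecessor_sets(centers, C, mode)
    psi = build_correlation_sets(pi, C, J)
    return ExpertGraph(
        J=J, B=B, C=C, gamma=gamma, consecutive=(mode == "consecutive"),
        partition=[np.sort(sets[j]) for j in order],
        inducing_idx=inducing, centers=centers, pi=pi, psi=psi, order=order,
    )
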