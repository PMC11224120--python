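"""Community detection with restart consensus at subject and group level.

The analysis treats each thresholded connectivity graph as an undirected
network and asks how cleanly it splits into modules. Three layers are built on
one another:

* :func:`modularity_q` — Newman modularity ``Q = sum_m (e_mm/E - (d_m/2E)^2)``
  for a given partition, the segregation index compared across conditions.
* :func:`louvain` / :func:`best_partition` — greedy stochastic maximisation of
  Q with many restarts; the best-Q partition is kept and a co-assignment
  (agreement) matrix is accumulated over *all* restarts.
* :func:`consensus_partition` — iterative re-clustering of an agreement matrix
  (weak entries below ``tau`` zeroed) until the partition is reproducible,
  the standard consensus-clustering construction.

Group-level structure per condition comes from
:func:`group_probability_matrix` (probability that two nodes share a module
across subjects) followed by :func:`consensus_partition`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._louvain import local_move

logger = logging.getLogger(__name__)

#: modules with at most this many nodes are reported as "unassigned"
SMALL_MODULE_SIZE = 3


# ---------------------------------------------------------------------------
# partitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Partition:
    """A node -> module assignment with contiguous 1-based module ids.

    ``labels[i]`` is the module of node ``i``. Labels are canonicalised by
    first occurrence, so two partitions that are relabelings of each other
    compare equal. Modules with ``<= SMALL_MODULE_SIZE`` nodes are retained
    but flagged via :meth:`small_modules` for reporting.
    """

    labels: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "labels", canonical_labels(self.labels))
        self.labels.setflags(write=False)

    @property
    def n_nodes(self) -> int:
        return self.labels.size

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0

    @property
    def module_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def members(self, module_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == module_id)

    def small_modules(self, max_size: int = SMALL_MODULE_SIZE) -> list[int]:
        """Module ids too small to be reported as modules ("unassigned")."""
        return [m for m, s in self.module_sizes.items() if s <= max_size]

    def large_modules(self, min_size: int = SMALL_MODULE_SIZE + 1) -> list[int]:
        return [m for m, s in self.module_sizes.items() if s >= min_size]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return np.array_equal(self.labels, other.labels)

    def __hash__(self):
        return hash(self.labels.tobytes())


def canonical_labels(labels) -> np.ndarray:
    """Relabel to contiguous 1-based ids in order of first occurrence."""
    labels = np.asarray(labels)
    if labels.ndim != 1 or labels.size == 0:
        raise ValueError("labels must be a non-empty 1-d array")
    _, first, inverse = np.unique(labels, return_index=True, return_inverse=True)
    # rank unique values by first occurrence
    order = np.argsort(np.argsort(first))
    return (order[inverse] + 1).astype(np.int64)


@dataclass
class AgreementMatrix:
    """Node x node co-assignment probabilities.

    ``level`` records whether entries are frequencies across Louvain restarts
    of one subject ("subject") or across subjects ("group"); ``n_samples`` is
    the number of partitions aggregated.
    """

    values: np.ndarray
    level: str = "subject"
    n_samples: int = 0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("agreement matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("agreement matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("agreement entries must lie in [0, 1]")
        self.values = v


@dataclass
class ModularityResult:
    """Best-of-``n_restarts`` Louvain outcome for one graph."""

    q_max: float
    best_partition: Partition
    agreement: AgreementMatrix
    n_restarts: int
    density: float | None = None
    seed: object = None


@dataclass
class ConsensusResult:
    partition: Partition
    n_iterations: int
    converged: bool


# ---------------------------------------------------------------------------
# modularity index
# ---------------------------------------------------------------------------


def _as_adjacency(graph) -> np.ndarray:
    A = np.asarray(getattr(graph, "adjacency", graph), dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    return A


def modularity_q(graph, partition, gamma: float = 1.0) -> float:
    """Newman modularity of ``partition`` on an undirected (weighted) graph.

    For binary graphs this is ``sum_m (e_mm/E - (d_m / 2E)^2)`` with ``E`` the
    edge count, ``e_mm`` the intra-module edge count and ``d_m`` the degree
    sum of module ``m``; the weighted generalisation replaces counts by
    strengths. Diagonal entries are treated as self-loop weight already
    counted twice (the aggregation convention used internally).
    """
    A = _as_adjacency(graph)
    labels = partition.labels if isinstance(partition, Partition) else canonical_labels(partition)
    if labels.size != A.shape[0]:
        raise ValueError("partition size does not match graph")
    twom = A.sum()
    if twom <= 0:
        raise ValueError("graph has no edges")
    k = A.sum(axis=1)
    q = 0.0
    for m in np.unique(labels):
        idx = labels == m
        q += A[np.ix_(idx, idx)].sum() / twom - gamma * (k[idx].sum() / twom) ** 2
    return float(q)


# ---------------------------------------------------------------------------
# Louvain
# ---------------------------------------------------------------------------


def louvain(graph, seed=0, gamma: float = 1.0, return_trace: bool = False):
    """Greedy Louvain maximisation of Q with seeded random sweep order.

    Returns ``(Partition, q)``; with ``return_trace=True`` also the Q value
    after each level, which is non-decreasing by construction. Isolated nodes
    stay singletons.
    """
    A = _as_adjacency(graph).astype(float)
    if A.sum() <= 0:
        raise ValueError("graph has no edges")
    rng = np.random.default_rng(seed)
    n0 = A.shape[0]
    labels_full = np.arange(n0, dtype=np.int64)
    B = A.copy()
    trace: list[float] = []
    while True:
        n = B.shape[0]
        twom = B.sum()
        k = B.sum(axis=1)
        comm = np.arange(n, dtype=np.int64)
        ctot = k.copy()
        order = rng.permutation(n).astype(np.int64)
        n_moves = local_move(B, k, ctot, comm, order, float(twom), float(gamma))
        if n_moves == 0:
            if not trace:
                trace.append(modularity_q(A, labels_full + 1, gamma=gamma))
            break
        _, inv = np.unique(comm, return_inverse=True)
        labels_full = inv[labels_full]
        nc = inv.max() + 1
        P = np.zeros((n, nc))
        P[np.arange(n), inv] = 1.0
        B = P.T @ B @ P
        trace.append(modularity_q(A, labels_full + 1, gamma=gamma))
    part = Partition(labels_full + 1)
    q = trace[-1]
    if return_trace:
        return part, q, trace
    return part, q


def best_partition(graph, n_restarts: int = 1000, seed=0, gamma: float = 1.0,
                   density: float | None = None) -> ModularityResult:
    """Run :func:`louvain` ``n_restarts`` times; keep the highest-Q partition.

    The agreement matrix is accumulated over all restarts (not only the
    best), giving per-pair co-assignment frequencies.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    A = _as_adjacency(graph)
    n = A.shape[0]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_restarts)
    agree = np.zeros((n, n))
    best_q = -np.inf
    best: Partition | None = None
    for child in children:
        part, q = louvain(A, seed=child, gamma=gamma)
        agree += part.labels[:, None] == part.labels[None, :]
        if q > best_q + 1e-15:
            best_q = q
            best = part
    agree /= n_restarts
    np.fill_diagonal(agree, 1.0)
    return ModularityResult(
        q_max=float(best_q),
        best_partition=best,
        agreement=AgreementMatrix(agree, level="subject", n_samples=n_restarts),
        n_restarts=n_restarts,
        density=density,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------


def _consensus_labels(agreement: np.ndarray, ss: np.random.SeedSequence,
                      tau: float, n_restarts: int, max_iter: int, gamma: float):
    """Iterative consensus re-clustering; returns (labels, n_iter, converged)."""
    W = np.array(agreement, dtype=float)
    n = W.shape[0]
    for it in range(1, max_iter + 1):
        Wt = W.copy()
        Wt[Wt < tau] = 0.0
        np.fill_diagonal(Wt, 0.0)
        if Wt.sum() == 0.0:
            return np.arange(1, n + 1, dtype=np.int64), it, True
        sub = ss.spawn(n_restarts)
        parts = [louvain(Wt, seed=s, gamma=gamma)[0] for s in sub]
        first = parts[0]
        if all(p == first for p in parts[1:]):
            return first.labels.copy(), it, True
        W = np.zeros((n, n))
        for p in parts:
            W += p.labels[:, None] == p.labels[None, :]
        W /= len(parts)
    return parts[0].labels.copy(), max_iter, False


def consensus_partition(agreement, seed=0, tau: float = 0.4,
                        n_restarts: int = 100, max_iter: int = 20,
                        gamma: float = 1.0) -> ConsensusResult:
    """Consensus partition of an agreement matrix.

    The agreement matrix is thresholded at ``tau`` (weak co-assignments
    zeroed), clustered with ``n_restarts`` Louvain restarts, and — if the
    restarts disagree — replaced by their co-assignment matrix, iterating
    until every restart returns the identical partition. Non-convergence
    after ``max_iter`` iterations returns the last partition with
    ``converged=False`` and a warning.
    """
    values = agreement.values if isinstance(agreement, AgreementMatrix) else np.asarray(agreement, float)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    labels, n_iter, converged = _consensus_labels(values, ss, tau, n_restarts, max_iter, gamma)
    if not converged:
        logger.warning("consensus did not converge after %d iterations", n_iter)
    return ConsensusResult(Partition(labels), n_iter, converged)


def group_probability_matrix(subject_partitions) -> AgreementMatrix:
    """Probability that two nodes share a module across subjects."""
    parts = list(subject_partitions)
    if len(parts) < 2:
        raise ValueError("need at least 2 subjects")
    n = parts[0].n_nodes
    if any(p.n_nodes != n for p in parts):
        raise ValueError("subject partitions have mismatched node sets")
    M = np.zeros((n, n))
    for p in parts:
        M += p.labels[:, None] == p.labels[None, :]
    M /= len(parts)
    np.fill_diagonal(M, 1.0)
    return AgreementMatrix(M, level="group", n_samples=len(parts))


def group_consensus(subject_partitions, seed=0, tau: float = 0.4,
                    n_restarts: int = 100, max_iter: int = 20) -> ConsensusResult:
    """Group consensus partition: probability matrix -> consensus clustering."""
    return consensus_partition(group_probability_matrix(subject_partitions),
                               seed=seed, tau=tau, n_restarts=n_restarts,
                               max_iter=max_iter)
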