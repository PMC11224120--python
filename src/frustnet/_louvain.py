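"""Dense Louvain local-moving kernel.

The community-detection workload here is unusual: consensus clustering and the
permutation tests re-run Louvain tens of thousands of times on small (<=116
node) dense graphs, so the kernel operates on a dense adjacency matrix and is
compiled with numba. Self-loop weight accumulated during aggregation is stored
on the diagonal with the convention ``A[c, c] = 2 * internal weight`` so that
row sums remain node strengths and ``A.sum()`` remains ``2m``.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def local_move(B, k, ctot, comm, order, twom, gamma):
    """One Louvain level: sweep nodes in ``order`` until no move improves Q.

    Mutates ``comm`` (community id per node, initially arange) and ``ctot``
    (total strength per community) in place. Returns the number of moves.
    Ties in gain keep the current community (first strictly better wins),
    which makes the result deterministic for a fixed ``order``.
    """
    n = B.shape[0]
    nw = np.zeros(n)
    n_moves = 0
    improved = True
    while improved:
        improved = False
        for oi in range(n):
            i = order[oi]
            ci = comm[i]
            # strength from i to each neighbouring community
            for j in range(n):
                w = B[i, j]
                if w != 0.0 and j != i:
                    nw[comm[j]] += w
            ki = k[i]
            ctot[ci] -= ki
            best_c = ci
            best_gain = nw[ci] - gamma * ki * ctot[ci] / twom
            for j in range(n):
                if B[i, j] != 0.0 and j != i:
                    c = comm[j]
                    if c != best_c:
                        g = nw[c] - gamma * ki * ctot[c] / twom
                        if g > best_gain + 1e-12:
                            best_gain = g
                            best_c = c
            ctot[best_c] += ki
            if best_c != ci:
                comm[i] = best_c
                improved = True
                n_moves += 1
            # reset scratch (assignment handles duplicate neighbours; only
            # entries at neighbour communities were ever written)
            for j in range(n):
                if B[i, j] != 0.0 and j != i:
                    nw[comm[j]] = 0.0
            nw[ci] = 0.0
    return n_moves
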