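"""Blended node-similarity matrix combining sequence scores with topology.

The cross-network score used to seed the search is a convex blend

    S = alpha * B  +  (1 - alpha) * A1 @ B @ A2.T

where ``B`` holds sequence-similarity scores (rows = source nodes, columns =
target nodes) and ``A1``, ``A2`` are the two adjacency matrices, so the
second term sums, for each candidate pair (i, j), the sequence scores over
all neighbor pairs (u, v) with u adjacent to i and v adjacent to j.

Raw bit-scores and neighbor sums live on very different scales, so each term
is max-normalized into [0, 1] before blending; ``alpha`` is then a genuine
convex weight between sequence and topological evidence (alpha = 1 means
sequence only).
"""

from __future__ import annotations

import numpy as np

from .io_formats import Network

__all__ = ["max_normalize", "topology_term", "blended_similarity",
           "DEFAULT_ALPHA"]

DEFAULT_ALPHA = 0.4


def max_normalize(matrix: np.ndarray) -> np.ndarray:
    """Divide by the global maximum; an all-zero matrix is returned as a copy."""
    matrix = np.asarray(matrix, dtype=float)
    mx = matrix.max() if matrix.size else 0.0
    if mx > 0:
        return matrix / mx
    return matrix.copy()


def topology_term(B: np.ndarray, net1: Network, net2: Network) -> np.ndarray:
    """Neighbor-summed similarity: entry (i, j) = sum of B[u, v] over
    neighbors u of i in net1 and neighbors v of j in net2.

    Computed as the dense triple product A1 @ B @ A2.T.
    """
    B = np.asarray(B, dtype=float)
    if B.shape != (net1.n, net2.n):
        raise ValueError(f"similarity shape {B.shape} does not match "
                         f"networks ({net1.n}, {net2.n})")
    return net1.adjacency @ B @ net2.adjacency.T


def blended_similarity(B: np.ndarray, net1: Network, net2: Network,
                       alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Blend max-normalized sequence and topology terms with weight ``alpha``.

    Returns a matrix with entries in [0, 1]; all-zero input yields an
    all-zero blend.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    Bn = max_normalize(B)
    if Bn.shape != (net1.n, net2.n):
        raise ValueError(f"similarity shape {Bn.shape} does not match "
                         f"networks ({net1.n}, {net2.n})")
    T = max_normalize(topology_term(Bn, net1, net2))
    return alpha * Bn + (1.0 - alpha) * T
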