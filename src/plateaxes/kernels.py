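"""k-nearest-neighbor graphs and adaptive Gaussian kernels.

One kernel construction is shared by the diffusion map, the absorbing
Markov-chain classifier, the autocorrelation weights and diffusion
imputation, so that every stage sees the same notion of cell-cell
similarity: a kNN graph with per-cell adaptive bandwidth set to the
distance of the ka-th neighbor.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .containers import NeighborGraph

# above this size exact all-pairs search is replaced by a tree search
_BRUTE_FORCE_MAX = 4096


def knn_graph(X: np.ndarray, k: int = 30) -> NeighborGraph:
    """Directed Euclidean kNN graph, self excluded.

    Ties in distance are broken by ascending cell index, which makes the
    graph deterministic even for duplicated points.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if not np.all(np.isfinite(X)):
        raise ValueError("input contains non-finite values")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    if n <= _BRUTE_FORCE_MAX:
        d2 = np.maximum(
            (X * X).sum(1)[:, None] + (X * X).sum(1)[None, :] - 2.0 * X @ X.T, 0.0
        )
        np.fill_diagonal(d2, np.inf)
        # stable argsort on distance; equal distances resolve by index
        order = np.argsort(d2, axis=1, kind="stable")[:, :k]
        dist = np.sqrt(np.take_along_axis(d2, order, axis=1))
        return NeighborGraph(indices=order, distances=dist, k=k)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    # drop self (always at distance 0 in the first column for exact search)
    keep_idx = np.empty((n, k), dtype=int)
    keep_dist = np.empty((n, k))
    for i in range(n):
        mask = idx[i] != i
        keep_idx[i] = idx[i][mask][:k]
        keep_dist[i] = dist[i][mask][:k]
    return NeighborGraph(indices=keep_idx, distances=keep_dist, k=k)


def adaptive_bandwidths(graph: NeighborGraph, ka: int) -> np.ndarray:
    """Per-cell bandwidth = distance to the ka-th nearest neighbor.

    A zero bandwidth (duplicated points) falls back to the smallest
    positive neighbor distance of that cell, or 1.0 if all neighbors
    coincide with the cell.
    """
    if ka < 1 or ka > graph.k:
        raise ValueError(f"ka={ka} must be in [1, k={graph.k}]")
    sigma = graph.distances[:, ka - 1].copy()
    for i in np.flatnonzero(sigma == 0):
        pos = graph.distances[i][graph.distances[i] > 0]
        sigma[i] = pos.min() if pos.size else 1.0
    return sigma


def adaptive_affinity(graph: NeighborGraph, ka: int | None = None) -> sp.csr_matrix:
    """Symmetric adaptive Gaussian affinity on the kNN graph.

    a_ij = exp(-d_ij^2 / sigma_i^2) for j in kNN(i); symmetrized by the
    arithmetic mean.  Zero diagonal; support is the symmetrized edge set.
    """
    if ka is None:
        ka = max(1, graph.k // 3)
    sigma = adaptive_bandwidths(graph, ka)
    n, k = graph.indices.shape
    rows = np.repeat(np.arange(n), k)
    cols = graph.indices.ravel()
    vals = np.exp(-(graph.distances.ravel() ** 2) / (sigma[rows] ** 2))
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    A = (A + A.T) * 0.5
    A.setdiag(0.0)
    A.eliminate_zeros()
    return A


def row_stochastic(A: sp.spmatrix) -> sp.csr_matrix:
    """Row-normalize a non-negative matrix to a Markov transition matrix."""
    A = sp.csr_matrix(A, dtype=float)
    rowsum = np.asarray(A.sum(axis=1)).ravel()
    if np.any(rowsum <= 0):
        raise ValueError("row with zero total affinity; graph has isolated cells")
    D_inv = sp.diags(1.0 / rowsum)
    return sp.csr_matrix(D_inv @ A)
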