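"""Selection of spatially informative genes by local autocorrelation.

For each gene, expression is standardized across cells and the test
statistic is the sum of edge-weighted pairwise products over the
symmetric kNN kernel graph of a latent space (a single diffusion
component or the multiscale embedding):

    H = sum_{i<j} w_ij x_i x_j

Under the null that expression is independent of graph position,
E[H] = -S0 / (n - 1) (the small negative offset induced by
standardizing x to zero mean, with S0 = sum_{i<j} w_ij) and
Var[H] = sum_{i<j} w_ij^2; Z = (H - E[H]) / sd and the one-sided p
targets positive autocorrelation.  A permutation oracle is provided to
validate the analytic null.  Genes are selected by a log-expression
range filter (> 1), an FDR cutoff (< 1e-5) and a Z threshold (>= 10 by
default, or chosen by knee point on the sorted Z curve).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import Embedding, NormMatrix
from .kernels import adaptive_affinity, adaptive_bandwidths, knn_graph

Z_MIN_DEFAULT = 10.0
FDR_MAX_DEFAULT = 1e-5
RANGE_MIN_DEFAULT = 1.0


def neighbor_weights(latent: Embedding | np.ndarray, k: int = 30,
                     ka: int | None = None) -> sp.csr_matrix:
    """Symmetric autocorrelation weights on a latent space.

    Adaptive Gaussian kernel on the kNN graph, per-cell outgoing
    weights normalized to sum 1, then symmetrized by the arithmetic
    mean; zero diagonal.
    """
    X = latent.values if isinstance(latent, Embedding) else np.asarray(latent, float)
    if X.ndim == 1:
        X = X[:, None]
    if ka is None:
        ka = max(1, k // 3)
    graph = knn_graph(X, k=k)
    sigma = adaptive_bandwidths(graph, ka)
    n, kk = graph.indices.shape
    rows = np.repeat(np.arange(n), kk)
    cols = graph.indices.ravel()
    vals = np.exp(-(graph.distances.ravel() ** 2) / (sigma[rows] ** 2))
    W = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    rowsum = np.asarray(W.sum(axis=1)).ravel()
    W = sp.diags(1.0 / np.maximum(rowsum, 1e-300)) @ W
    W = (W + W.T) * 0.5
    W = sp.csr_matrix(W)
    W.setdiag(0.0)
    W.eliminate_zeros()
    return W


def _standardize(x: np.ndarray) -> np.ndarray | None:
    sd = x.std()
    if sd == 0:
        return None
    return (x - x.mean()) / sd


def _null_moments(W: sp.csr_matrix) -> tuple[float, float]:
    n = W.shape[0]
    s0 = W.sum() / 2.0
    var = (W.multiply(W)).sum() / 2.0
    mean = -s0 / (n - 1)
    return float(mean), float(var)


def local_autocorrelation(W: sp.csr_matrix, x: np.ndarray) -> tuple[float, float, float]:
    """(H, Z, one-sided p) for one gene's expression vector."""
    xs = _standardize(np.asarray(x, dtype=float))
    if xs is None:
        return 0.0, 0.0, 1.0
    H = float(xs @ (W @ xs)) / 2.0
    mean0, var0 = _null_moments(W)
    Z = (H - mean0) / np.sqrt(var0)
    return H, float(Z), float(stats.norm.sf(Z))


def autocorrelation_table(W: sp.csr_matrix, norm: NormMatrix,
                          latent_name: str = "latent") -> pd.DataFrame:
    """Vectorized H/Z/p/log-range for every gene against one weight
    matrix; BH-FDR computed across genes passing the range filter."""
    X = norm.X
    n = X.shape[0]
    mean0, var0 = _null_moments(W)
    sd = X.std(axis=0)
    ok = sd > 0
    Xs = np.zeros_like(X)
    Xs[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    H = np.einsum("ij,ij->j", W @ Xs, Xs) / 2.0
    Z = np.where(ok, (H - mean0) / np.sqrt(var0), 0.0)
    H = np.where(ok, H, 0.0)
    p = np.where(ok, stats.norm.sf(Z), 1.0)
    log_range = X.max(axis=0) - X.min(axis=0)

    tab = pd.DataFrame({
        "H": H, "Z": Z, "p": p, "log_range": log_range,
    }, index=norm.genes)
    tab["latent"] = latent_name
    tab["fdr"] = np.nan
    in_range = tab["log_range"] > RANGE_MIN_DEFAULT
    if in_range.any():
        tab.loc[in_range, "fdr"] = multipletests(
            tab.loc[in_range, "p"], method="fdr_bh")[1]
    return tab


def permutation_null(W: sp.csr_matrix, x: np.ndarray, n_perm: int = 1000,
                     seed: int = 0) -> tuple[float, float]:
    """Empirical z and p of H under random cell permutations (oracle
    for the analytic null)."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    xs = _standardize(np.asarray(x, dtype=float))
    if xs is None:
        return 0.0, 1.0
    rng = np.random.default_rng(seed)
    H_obs = float(xs @ (W @ xs)) / 2.0
    H_perm = np.empty(n_perm)
    for b in range(n_perm):
        xp = xs[rng.permutation(len(xs))]
        H_perm[b] = float(xp @ (W @ xp)) / 2.0
    sd = H_perm.std(ddof=1)
    z = (H_obs - H_perm.mean()) / sd if sd > 0 else 0.0
    p_emp = (1 + np.sum(H_perm >= H_obs)) / (n_perm + 1)
    return float(z), float(p_emp)


def select_spatial_genes(results: pd.DataFrame, z_min: float | None = Z_MIN_DEFAULT,
                         fdr_max: float = FDR_MAX_DEFAULT,
                         range_min: float = RANGE_MIN_DEFAULT,
                         use_knee: bool = False) -> pd.DataFrame:
    """Apply the selection rule; returns the table with a ``selected``
    flag and the threshold actually used in ``attrs['z_min']``.

    Genes with log range <= ``range_min`` are excluded outright; the
    remainder are selected iff FDR < ``fdr_max`` and Z >= the threshold
    (inclusive).  With ``use_knee`` the Z threshold is chosen by knee
    point on the descending sorted Z curve of all range-passing genes.
    """
    from .modules import knee_point

    tab = results.copy()
    in_range = tab["log_range"] > range_min
    if use_knee or z_min is None:
        z_sorted = np.sort(tab.loc[in_range, "Z"].to_numpy())[::-1]
        if z_sorted.size < 3:
            warnings.warn("too few genes for knee point; using default Z >= 10")
            z_min = Z_MIN_DEFAULT
        else:
            z_min = float(z_sorted[knee_point(np.arange(z_sorted.size),
                                              z_sorted)])
    tab["selected"] = (in_range & (tab["fdr"] < fdr_max) & (tab["Z"] >= z_min))
    if not tab["selected"].any():
        warnings.warn("no genes selected as spatially informative")
    tab.attrs["z_min"] = float(z_min)
    return tab
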