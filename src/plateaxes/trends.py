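"""Diffusion imputation, spline trend fitting and trend clustering.

Expression is optionally de-noised by diffusion imputation (t steps of
the cell-cell Markov chain, k=5 adaptive kernel), then each gene is fit
against a diffusion-component axis with a penalized cubic B-spline
regression (knots at component quantiles, smoothing chosen per gene by
generalized cross-validation) and evaluated at 500 equally spaced bins
on the min-max normalized axis.  Trends are z-normalized and clustered
as graph communities on a correlation-distance kNN graph (k=20).

Imputed values are used for trend fitting and display only; selection
statistics and differential expression always run on non-imputed
values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .containers import Embedding, NeighborGraph, NormMatrix
from .clustering import ClusterAssignment, community_detect
from .kernels import adaptive_affinity, knn_graph, row_stochastic

N_BINS_DEFAULT = 500
LAMBDA_GRID = 10.0 ** np.arange(-4.0, 5.0)


@dataclass
class TrendMatrix:
    values: np.ndarray      # genes x bins
    bins: np.ndarray        # bin centers on the normalized [0, 1] axis
    genes: pd.Index
    normalization: str = "none"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bins) <= 0):
            raise ValueError("bin centers must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite trend values")

    def znorm(self) -> "TrendMatrix":
        mu = self.values.mean(axis=1, keepdims=True)
        sd = self.values.std(axis=1, keepdims=True)
        vals = np.where(sd > 0, (self.values - mu) / np.maximum(sd, 1e-300), 0.0)
        return TrendMatrix(vals, self.bins, self.genes, "z_per_gene")


def impute_diffusion(norm: NormMatrix, latent: Embedding | np.ndarray,
                     k: int = 5, t: int = 3) -> NormMatrix:
    """Smooth expression by t steps of the latent-space Markov chain."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return NormMatrix(norm.X.copy(), norm.cells, norm.genes,
                          provenance=norm.provenance + ["imputed:t=0"])
    X = latent.values if isinstance(latent, Embedding) else np.asarray(latent, float)
    if X.ndim == 1:
        X = X[:, None]
    graph = knn_graph(X, k=k)
    P = row_stochastic(adaptive_affinity(graph, ka=max(1, k // 3)))
    out = norm.X
    for _ in range(t):
        out = P @ out
    return NormMatrix(np.asarray(out), norm.cells, norm.genes,
                      provenance=norm.provenance + [f"imputed:k={k},t={t}"])


def _spline_basis(u: np.ndarray, n_knots: int) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline design matrix with interior knots at quantiles of
    u (values in [0, 1]); returns (basis, knot vector)."""
    interior = np.unique(np.quantile(u, np.linspace(0, 1, n_knots + 2)[1:-1]))
    knots = np.concatenate([[0.0] * 4, interior, [1.0] * 4])
    B = BSpline.design_matrix(np.clip(u, 0.0, 1.0), knots, 3).toarray()
    return B, knots


def fit_trend(values: np.ndarray, component: np.ndarray,
              n_bins: int = N_BINS_DEFAULT, n_knots: int = 8,
              lambdas: np.ndarray = LAMBDA_GRID) -> TrendMatrix:
    """Penalized cubic-spline trends of one or more genes along an axis.

    ``values``: (cells,) or (cells, genes) expression; ``component``:
    per-cell axis values (min-max normalized internally).  Smoothing is
    selected per gene by GCV over a fixed lambda grid with a
    second-difference coefficient penalty.
    """
    Y = np.asarray(values, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    comp = np.asarray(component, dtype=float)
    n = comp.size
    if Y.shape[0] != n:
        raise ValueError("values and component lengths differ")
    if n < 20:
        raise ValueError("need at least 20 cells to fit trends")
    rng = np.ptp(comp)
    if rng == 0:
        raise ValueError("component values are constant")
    u = (comp - comp.min()) / rng

    nb_target = n_knots + 4
    while nb_target >= n and n_knots > 1:
        n_knots -= 1
        nb_target = n_knots + 4
        warnings.warn("reducing spline knots to fit the number of cells")
    B, knots = _spline_basis(u, n_knots)
    nb = B.shape[1]
    D = np.diff(np.eye(nb), n=2, axis=0)
    penalty = D.T @ D
    BtB = B.T @ B
    BtY = B.T @ Y

    bins = (np.arange(n_bins) + 0.5) / n_bins
    Bp = BSpline.design_matrix(bins, knots, 3, extrapolate=True).toarray()

    best_gcv = np.full(Y.shape[1], np.inf)
    best_pred = np.empty((Y.shape[1], n_bins))
    for lam in np.atleast_1d(lambdas):
        M = BtB + lam * penalty
        try:
            coef = np.linalg.solve(M, BtY)
        except np.linalg.LinAlgError:
            continue
        fitted = B @ coef
        rss = ((Y - fitted) ** 2).sum(axis=0)
        edf = np.trace(np.linalg.solve(M, BtB))
        gcv = n * rss / max(n - edf, 1e-8) ** 2
        better = gcv < best_gcv
        if np.any(better):
            pred = (Bp @ coef).T
            best_pred[better] = pred[better]
            best_gcv[better] = gcv[better]
    return TrendMatrix(best_pred, bins, pd.RangeIndex(Y.shape[1]))


def fit_gene_trends(norm: NormMatrix, component: np.ndarray,
                    genes: list[str] | None = None,
                    n_bins: int = N_BINS_DEFAULT) -> TrendMatrix:
    """Trend matrix for a gene list along one component axis."""
    if genes is None:
        genes = list(norm.genes)
    cols = [norm.genes.get_loc(g) for g in genes]
    tm = fit_trend(norm.X[:, cols], component, n_bins=n_bins)
    return TrendMatrix(tm.values, tm.bins, pd.Index(genes, name="gene"))


def cluster_trends(trends: TrendMatrix, k: int = 20,
                   seed: int = 0) -> ClusterAssignment:
    """Graph communities of z-normalized trends under correlation
    distance (1 - Pearson across bins); cluster count is emergent.

    Zero-variance trends are assigned to their own singleton clusters,
    flagged in ``params['flat_genes']``.
    """
    n_genes = trends.values.shape[0]
    if n_genes < k + 1:
        raise ValueError(f"need more than k={k} genes to cluster trends")
    sd = trends.values.std(axis=1)
    flat = sd == 0
    z = trends.znorm().values
    active = np.flatnonzero(~flat)
    if active.size < 2:
        raise ValueError("fewer than 2 non-constant trends")
    C = np.corrcoef(z[active])
    dist = 1.0 - C
    np.fill_diagonal(dist, np.inf)
    kk = min(k, active.size - 1)
    order = np.argsort(dist, axis=1, kind="stable")[:, :kk]
    dvals = np.take_along_axis(dist, order, axis=1)
    graph = NeighborGraph(indices=order, distances=dvals, k=kk)
    sub = community_detect(graph, seed=seed)
    labels = np.empty(n_genes, dtype=int)
    labels[active] = sub.labels
    next_id = sub.n_clusters
    for g in np.flatnonzero(flat):
        labels[g] = next_id
        next_id += 1
    return ClusterAssignment(labels, next_id,
                             params={"k": k, "seed": seed,
                                     "flat_genes": list(trends.genes[flat])})
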