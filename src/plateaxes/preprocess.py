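"""Normalization, program regression, HVG selection, PCA and kNN graph.

Normalization follows the standard single-cell recipe: per-cell counts
are scaled to the median library size and natural-log transformed with
pseudocount 1.  Program (e.g. cell-cycle) influence is removed by
per-gene ordinary least squares on per-cell program scores, preserving
gene means.  Highly variable genes are selected by a
variance-stabilizing ranking (loess mean-variance trend, clipped
standardized counts), principal components are kept up to 75% of
variance and the cell kNN graph is built on that embedding.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
import statsmodels.api as sm
from sklearn.decomposition import PCA

from .containers import CountMatrix, Embedding, NeighborGraph, NormMatrix
from .kernels import knn_graph as _knn

__all__ = [
    "normalize_median_log1p", "regress_out_programs", "select_hvgs",
    "pca_75", "knn_graph",
]


def normalize_median_log1p(counts: CountMatrix) -> NormMatrix:
    """x_cg = ln(1 + m * c_cg / L_c), m = median library size."""
    lib = counts.library_sizes().astype(float)
    if np.any(lib <= 0):
        raise ValueError("cells with zero library size; filter them first")
    m = float(np.median(lib))
    X = counts.X.multiply((m / lib)[:, None]).toarray()
    np.log1p(X, out=X)
    return NormMatrix(X, counts.cells, counts.genes,
                      provenance=["median_libsize_norm", "log1p"])


def regress_out_programs(norm: NormMatrix, program_scores: np.ndarray,
                         program_names: list[str] | None = None) -> NormMatrix:
    """Remove per-cell program covariates from every gene by OLS.

    Scores are centered, so the returned matrix keeps each gene's mean
    exactly (residual-plus-intercept form).
    """
    S = np.atleast_2d(np.asarray(program_scores, dtype=float))
    if S.shape[0] != norm.n_cells:
        S = S.T
    if S.shape[0] != norm.n_cells:
        raise ValueError("program scores do not align with cells")
    if not np.all(np.isfinite(S)):
        raise ValueError("non-finite program scores")
    if norm.n_cells < S.shape[1] + 2:
        raise ValueError("need at least 2 more cells than programs")
    Sc = S - S.mean(axis=0)
    gram = Sc.T @ Sc
    rank = np.linalg.matrix_rank(gram)
    if rank < Sc.shape[1]:
        names = program_names or [f"program{i}" for i in range(S.shape[1])]
        raise ValueError(f"collinear program scores among {names}")
    beta = np.linalg.solve(gram, Sc.T @ norm.X)
    resid = norm.X - Sc @ beta
    names = program_names or [f"program{i}" for i in range(S.shape[1])]
    return NormMatrix(resid, norm.cells, norm.genes,
                      provenance=norm.provenance + [f"regressed:{','.join(names)}"])


def _loess_trend(log_mean: np.ndarray, log_var: np.ndarray,
                 span: float = 0.3) -> np.ndarray:
    """Locally weighted fit of log10 variance on log10 mean."""
    fit = sm.nonparametric.lowess(log_var, log_mean, frac=span,
                                  return_sorted=False)
    return fit


def select_hvgs(counts: CountMatrix, n_top: int = 3000,
                always_keep: list[str] | None = None,
                min_cells: int = 10) -> list[str]:
    """Variance-stabilizing HVG ranking on raw counts.

    A loess trend of log10 variance on log10 mean gives each gene an
    expected standard deviation; counts standardized by it are clipped
    at sqrt(n_cells) and genes are ranked by the variance of the clipped
    values.  Mitochondrial (mt-), ribosomal (Rps/Rpl) and genes detected
    in fewer than ``min_cells`` cells are excluded before ranking;
    ``always_keep`` markers are appended if not already selected.
    """
    X = counts.X.tocsc()
    n = counts.n_cells
    n_detected = np.asarray((X > 0).sum(axis=0)).ravel()
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = (sq - mean**2) * n / max(n - 1, 1)

    names = counts.genes
    lowered = names.str.lower()
    excluded = np.asarray(lowered.str.startswith("mt-")
                          | lowered.str.startswith(("rps", "rpl"))
                          | (n_detected < min_cells))
    usable = np.flatnonzero(~excluded)
    if usable.size == 0:
        raise ValueError("no genes pass the HVG exclusion filters")

    # constant genes have standardized variance 0 and rank last; only
    # variable genes inform the mean-variance trend
    variable = usable[(var[usable] > 0) & (mean[usable] > 0)]
    constant = usable[~((var[usable] > 0) & (mean[usable] > 0))]
    est_var = 10.0 ** _loess_trend(np.log10(mean[variable]),
                                   np.log10(var[variable]))
    est_sd = np.sqrt(np.maximum(est_var, 1e-12))
    clip = np.sqrt(n)
    score = np.zeros(variable.size)
    for pos, g in enumerate(variable):
        col = X[:, g].toarray().ravel()
        z = (col - mean[g]) / est_sd[pos]
        np.clip(z, -clip, clip, out=z)
        score[pos] = z.var()
    order = np.concatenate([variable[np.argsort(-score, kind="stable")],
                            constant])
    if n_top > order.size:
        warnings.warn(f"requested {n_top} HVGs but only {order.size} genes usable")
    selected = [names[g] for g in order[:n_top]]
    for marker in (always_keep or []):
        if marker not in selected:
            if marker not in names:
                raise KeyError(f"always-keep marker {marker!r} not in gene universe")
            selected.append(marker)
    return selected


def pca_75(norm: NormMatrix, hvgs: list[str] | None = None,
           var_threshold: float = 0.75, max_components: int = 200) -> Embedding:
    """PCA on the (HVG-subset) log-normalized matrix; keep the smallest
    number of components whose cumulative variance share reaches the
    threshold."""
    if hvgs is not None:
        cols = [norm.genes.get_loc(g) for g in hvgs]
        X = norm.X[:, cols]
    else:
        X = norm.X
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 cells and 2 genes for PCA")
    total_var = X.var(axis=0, ddof=1).sum()
    if total_var <= 0:
        raise ValueError("zero total variance")
    n_comp = min(n - 1, p, max_components)
    pca = PCA(n_components=n_comp, svd_solver="auto", random_state=0)
    Y = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    if cum[-1] >= var_threshold:
        m = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    else:
        warnings.warn("variance threshold not reached within the computed "
                      "components; keeping all")
        m = n_comp
    return Embedding(Y[:, :m], kind="pca", cells=norm.cells,
                     variance_explained=ratios[:m])


def knn_graph(embedding: Embedding | np.ndarray, k: int = 30) -> NeighborGraph:
    """Euclidean kNN graph on an embedding (ties broken by cell index)."""
    X = embedding.values if isinstance(embedding, Embedding) else embedding
    return _knn(X, k=k)
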