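"""Multi-resolution gene-module discovery on spatially informative genes.

Each gene is represented by its row of the gene-gene Pearson
correlation matrix (computed on log-normalized expression); Ward
linkage on Euclidean distances between those rows yields a dendrogram.
The working cut is chosen by knee point on the curve of median
within-cluster pairwise correlation versus number of clusters, and
named coarser/finer cuts at fixed linkage heights (D = 10 / 6 / 4
analogues) expose broader or more refined spatial domains; cuts at
decreasing heights are nested refinements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .containers import NormMatrix
from .classify import SignatureSet, signature_score
from .clustering import ClusterAssignment


@dataclass
class Dendrogram:
    linkage: np.ndarray     # scipy linkage matrix (merge list)
    genes: pd.Index
    corr: np.ndarray        # gene-gene Pearson correlation matrix

    def cut(self, height: float) -> ClusterAssignment:
        return cut_modules(self, height)

    @property
    def max_height(self) -> float:
        return float(self.linkage[-1, 2])


def _relabel_by_size(raw: np.ndarray) -> np.ndarray:
    """Contiguous cluster ids ordered by decreasing size (stable ties)."""
    ids, counts = np.unique(raw, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[v] for v in raw], dtype=int)


def correlation_linkage(norm: NormMatrix, genes: list[str]) -> Dendrogram:
    """Ward dendrogram of genes over correlation-matrix rows.

    Constant genes cannot be correlated and are excluded with a
    warning.  The gene's self-correlation (1.0) is kept in its feature
    row, a fixed convention that keeps distances deterministic.
    """
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    cols = [norm.genes.get_loc(g) for g in genes]
    X = norm.X[:, cols]
    sd = X.std(axis=0)
    if np.any(sd == 0):
        dropped = [g for g, s in zip(genes, sd) if s == 0]
        warnings.warn(f"excluding {len(dropped)} constant genes from clustering")
        keep = sd > 0
        genes = [g for g, k in zip(genes, keep) if k]
        X, sd = X[:, keep], sd[keep]
        if len(genes) < 2:
            raise ValueError("fewer than 2 non-constant genes")
    C = np.corrcoef(X, rowvar=False)
    Z = hierarchy.linkage(C, method="ward", metric="euclidean")
    return Dendrogram(linkage=Z, genes=pd.Index(genes, name="gene"), corr=C)


def knee_point(x: np.ndarray, y: np.ndarray) -> int:
    """Index of maximum perpendicular distance to the chord joining the
    first and last points, after min-max normalizing both axes.

    Degenerate (straight-line) curves return the first interior index
    with a warning; ties resolve to the smallest index.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 points")

    def norm01(v):
        rng = np.ptp(v)
        return (v - v.min()) / rng if rng > 0 else np.zeros_like(v)

    xn, yn = norm01(x), norm01(y)
    p0 = np.array([xn[0], yn[0]])
    p1 = np.array([xn[-1], yn[-1]])
    chord = p1 - p0
    L = np.hypot(*chord)
    if L == 0:
        warnings.warn("degenerate knee curve (coincident endpoints)")
        return 1
    pts = np.column_stack([xn, yn]) - p0
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / L
    if np.allclose(dist, 0):
        warnings.warn("knee curve is a straight line; returning first "
                      "interior point")
        return 1
    return int(np.argmax(dist))


def _within_cluster_corr_curve(dend: Dendrogram,
                               c_max: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Median over clusters of mean pairwise within-cluster correlation,
    for increasing numbers of clusters."""
    n = len(dend.genes)
    cs = np.arange(2, min(c_max, n) + 1)
    med = np.empty(cs.size)
    C = dend.corr
    for i, c in enumerate(cs):
        raw = hierarchy.fcluster(dend.linkage, t=c, criterion="maxclust")
        means = []
        for cid in np.unique(raw):
            idx = np.flatnonzero(raw == cid)
            if idx.size < 2:
                means.append(1.0)
                continue
            block = C[np.ix_(idx, idx)]
            iu = np.triu_indices(idx.size, k=1)
            means.append(block[iu].mean())
        med[i] = np.median(means)
    return cs, med


def select_cut(dend: Dendrogram, c_max: int = 50) -> tuple[float, ClusterAssignment]:
    """Choose the working number of clusters by knee point on the
    median within-cluster correlation curve; returns (D_star, cut).

    D_star is the linkage height just above which the chosen number of
    clusters would merge further; the achieved median within-cluster
    correlation is reported in ``cut.params``.
    """
    # keep candidate cuts at an average module size of >= 5 genes so
    # the cohesion curve is not dominated by tiny near-perfect clusters
    c_max = max(2, min(c_max, len(dend.genes) // 5))
    cs, med = _within_cluster_corr_curve(dend, c_max=c_max)
    if np.ptp(med) < 1e-12:
        warnings.warn("flat correlation curve; degenerate data, using c*=2")
        c_star = 2
    elif cs.size < 3:
        c_star = int(cs[np.argmax(med)])
    else:
        # the knee rule assumes a monotone saturating curve; when
        # over-splitting dilutes cohesion the curve peaks in the
        # interior instead, and the peak is the natural cut
        m = int(np.argmax(med))
        if m < med.size - 1 and med[m] > med[-1] + 0.02:
            c_star = int(cs[m])
        else:
            c_star = int(cs[knee_point(cs, med)])
    n = len(dend.genes)
    heights = dend.linkage[:, 2]
    # any threshold in [heights[n-1-c_star], heights[n-c_star]) yields c_star
    d_star = float(heights[n - c_star]) if c_star > 1 else float("inf")
    raw = hierarchy.fcluster(dend.linkage, t=c_star, criterion="maxclust")
    labels = _relabel_by_size(raw)
    achieved = float(med[np.flatnonzero(cs == c_star)[0]])
    assignment = ClusterAssignment(labels, c_star,
                                   params={"D_star": d_star,
                                           "median_within_corr": achieved})
    return d_star, assignment


def cut_modules(dend: Dendrogram, D: float) -> ClusterAssignment:
    """Cut the dendrogram at linkage height D (merges with height <= D
    are applied); cluster ids ordered by decreasing size."""
    if D < 0:
        raise ValueError("cut height must be non-negative")
    raw = hierarchy.fcluster(dend.linkage, t=D, criterion="distance")
    labels = _relabel_by_size(raw)
    return ClusterAssignment(labels, len(np.unique(labels)),
                             params={"D": float(D)})


def module_score(norm: NormMatrix, module_genes: list[str]) -> np.ndarray:
    """Per-cell one-set signature z-score of a gene module."""
    if not module_genes:
        raise ValueError("empty module")
    return signature_score(norm, SignatureSet("module", list(module_genes)))
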