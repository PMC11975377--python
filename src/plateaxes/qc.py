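"""Cell quality-control cascade.

Four stages mirror a standard droplet scRNA-seq filtering recipe:

1. hard thresholds — library size > 1000 UMIs (strict) and
   mitochondrial fraction < 20% (strict);
2. a complexity filter — OLS of log10(genes detected) on log10(library
   size); cells more than 0.1 below the fitted line (residual < -0.1)
   are removed as low-complexity (e.g. stressed, one dominant program);
3. a kernel-density split of the log10 library-size distribution into
   high- and low-quality modes when it is bimodal;
4. cluster-level reassignment — cells are finely clustered (k=8 graph
   communities) and each cluster is Z-tested against the Gaussian fit
   of the high-quality mode; clusters with p < 1e-10 lying below the
   high mode are relabeled low quality wholesale.

Also provides exact without-replacement downsampling of libraries to a
common depth and a rank-sum DE screen between quality groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, NormMatrix

LIBRARY_MIN = 1000       # keep iff library > 1000 (strict)
MITO_MAX = 0.20          # keep iff mito fraction < 0.20 (strict)
COMPLEXITY_CUTOFF = -0.1  # remove iff OLS residual < -0.1
ZTEST_P_CUTOFF = 1e-10


def compute_cell_metrics(counts: CountMatrix,
                         mito_genes: list[str] | None = None) -> pd.DataFrame:
    """Per-cell library size, genes detected and mitochondrial fraction.

    ``mito_genes`` defaults to all genes whose name starts with "mt-"
    (case-insensitive).  All-zero cells get mito_frac = 0 by convention.
    """
    if counts.n_cells == 0 or counts.n_genes == 0:
        raise ValueError("empty count matrix")
    if mito_genes is None:
        mito_mask = counts.genes.str.lower().str.startswith("mt-")
        mito_genes = list(counts.genes[mito_mask])
    missing = set(mito_genes) - set(counts.genes)
    if missing:
        raise KeyError(f"mito genes not in gene universe: {sorted(missing)}")
    X = counts.X
    lib = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    mito_cols = [counts.genes.get_loc(g) for g in mito_genes]
    mito = (np.asarray(X[:, mito_cols].sum(axis=1)).ravel()
            if mito_cols else np.zeros_like(lib))
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(lib > 0, mito / np.maximum(lib, 1), 0.0)
    return pd.DataFrame({
        "library_size": lib.astype(int),
        "n_genes": n_genes.astype(int),
        "mito_frac": mito_frac,
    }, index=counts.cells)


def fit_complexity_model(metrics: pd.DataFrame,
                         cutoff: float = COMPLEXITY_CUTOFF) -> pd.DataFrame:
    """OLS of log10(n_genes) on log10(library_size); flags cells whose
    residual falls below ``cutoff`` (fewer genes than the library size
    predicts)."""
    ok = (metrics["library_size"] > 0) & (metrics["n_genes"] > 0)
    if ok.sum() < 10:
        raise ValueError("need >= 10 cells with positive library size")
    x = np.log10(metrics.loc[ok, "library_size"].to_numpy(dtype=float))
    y = np.log10(metrics.loc[ok, "n_genes"].to_numpy(dtype=float))
    if np.ptp(x) == 0:
        raise ValueError("zero-variance predictor (all library sizes equal)")
    slope, intercept = np.polyfit(x, y, 1)
    resid = pd.Series(np.nan, index=metrics.index, name="complexity_residual")
    resid.loc[ok] = y - (slope * x + intercept)
    out = metrics.copy()
    out["complexity_residual"] = resid
    out["complexity_keep"] = ~(resid < cutoff)  # NaN residual -> keep here
    return out


def threshold_filter(metrics: pd.DataFrame) -> pd.Index:
    """Cells passing the hard filters and the complexity filter."""
    m = metrics
    if "complexity_keep" not in m.columns:
        m = fit_complexity_model(m)
    keep = ((m["library_size"] > LIBRARY_MIN)
            & (m["mito_frac"] < MITO_MAX)
            & m["complexity_keep"])
    return m.index[keep]


@dataclass
class BimodalSplit:
    """Result of the KDE library-size split."""

    assignment: pd.Series        # "high" / "low" per cell
    antimode: float | None       # log10 library size, None if unimodal
    modes: list[float]


def split_bimodal_library(metrics: pd.DataFrame,
                          grid_size: int = 512) -> BimodalSplit:
    """Gaussian KDE (Silverman bandwidth) on log10 library size.

    If the density has two or more modes, the antimode is the minimum
    between the two highest modes; cells above it are assigned "high",
    below "low".  Unimodal distributions assign every cell "high".
    """
    lib = metrics["library_size"].to_numpy(dtype=float)
    if len(lib) < 100:
        raise ValueError("need >= 100 cells for the KDE split")
    logl = np.log10(np.maximum(lib, 1.0))
    kde = stats.gaussian_kde(logl, bw_method="silverman")
    grid = np.linspace(logl.min(), logl.max(), grid_size)
    dens = kde(grid)
    interior = np.arange(1, grid_size - 1)
    peaks = interior[(dens[interior] > dens[interior - 1])
                     & (dens[interior] >= dens[interior + 1])]
    modes = [float(grid[p]) for p in peaks]
    # a genuine second mode must be separated from the main mode by a
    # real valley (density dropping below 80% of the smaller peak);
    # this ignores shoulder wiggles of a single mode
    best_pair, best_height = None, 0.0
    for a in range(len(peaks)):
        for b in range(a + 1, len(peaks)):
            lo, hi = peaks[a], peaks[b]
            valley = dens[lo:hi + 1].min()
            smaller = min(dens[lo], dens[hi])
            if valley < 0.8 * smaller and smaller > best_height:
                best_pair, best_height = (lo, hi), smaller
    if best_pair is None:
        return BimodalSplit(pd.Series("high", index=metrics.index),
                            None, modes)
    lo, hi = best_pair
    between = np.arange(lo, hi + 1)
    antimode = float(grid[between[np.argmin(dens[between])]])
    assign = pd.Series(np.where(logl > antimode, "high", "low"),
                       index=metrics.index)
    return BimodalSplit(assign, antimode, modes)


def cluster_quality_reassignment(norm: NormMatrix, metrics: pd.DataFrame,
                                 mode_assignment: pd.Series, k: int = 8,
                                 p_cutoff: float = ZTEST_P_CUTOFF,
                                 seed: int = 0) -> pd.Series:
    """Relabel cells as high/low quality at the cluster level.

    Cells are finely clustered (graph communities on a k=8 kNN graph of
    a PCA of the normalized matrix).  Each cluster's mean log10 library
    size is Z-tested against the Gaussian fit of the high-quality mode
    (SE = sd / sqrt(cluster size)); a cluster becomes "low" only when
    it is both significantly below the high mode (p < 1e-10, two-sided)
    and more likely to come from the low mode than from the high mode
    (standardized distance to the low-mode Gaussian smaller), so that
    large clusters sitting marginally below the high-mode mean are not
    swept out on significance alone.
    """
    from .clustering import community_detect
    from .preprocess import knn_graph, pca_75

    logl = np.log10(np.maximum(
        metrics["library_size"].to_numpy(dtype=float), 1.0))
    high = (mode_assignment == "high").to_numpy()
    low = ~high
    if high.sum() < 2:
        raise ValueError("high-quality mode has fewer than 2 cells")
    mu_h, sd_h = logl[high].mean(), max(logl[high].std(ddof=1), 1e-12)
    if low.sum() >= 2:
        mu_l, sd_l = logl[low].mean(), max(logl[low].std(ddof=1), 1e-12)
    else:
        mu_l, sd_l = None, None

    emb = pca_75(norm)
    graph = knn_graph(emb, k=min(k, norm.n_cells - 1))
    clusters = community_detect(graph, seed=seed)
    labels = pd.Series("high", index=metrics.index)
    for cid in range(clusters.n_clusters):
        members = np.flatnonzero(clusters.labels == cid)
        if members.size == 1:
            labels.iloc[members] = mode_assignment.iloc[members].to_numpy()
            continue
        m_c = logl[members].mean()
        z = (m_c - mu_h) / (sd_h / np.sqrt(members.size))
        p = 2 * stats.norm.sf(abs(z))
        more_likely_low = (mu_l is not None
                           and abs(m_c - mu_l) / sd_l < abs(m_c - mu_h) / sd_h)
        if p < p_cutoff and m_c < mu_h and more_likely_low:
            labels.iloc[members] = "low"
    return labels


def run_qc(counts: CountMatrix, k: int = 8, seed: int = 0) -> pd.DataFrame:
    """Full QC cascade; returns the metrics table with a ``kept`` flag."""
    from .preprocess import normalize_median_log1p

    metrics = fit_complexity_model(compute_cell_metrics(counts))
    kept_hard = threshold_filter(metrics)
    metrics["hard_keep"] = metrics.index.isin(kept_hard)

    sub = counts.subset_cells(metrics["hard_keep"].to_numpy())
    sub_metrics = metrics.loc[metrics["hard_keep"]]
    if sub.n_cells >= 100:
        split = split_bimodal_library(sub_metrics)
        if split.antimode is not None:
            norm = normalize_median_log1p(sub)
            quality = cluster_quality_reassignment(
                norm, sub_metrics, split.assignment, k=k, seed=seed)
        else:
            quality = pd.Series("high", index=sub_metrics.index)
        metrics["mode"] = split.assignment.reindex(metrics.index)
    else:
        quality = pd.Series("high", index=sub_metrics.index)
        metrics["mode"] = pd.Series(dtype=object)
    metrics["quality"] = quality.reindex(metrics.index).fillna("low")
    metrics["kept"] = metrics["hard_keep"] & (metrics["quality"] == "high")
    return metrics


def downsample_counts(counts: CountMatrix, target: int,
                      seed: int = 0) -> CountMatrix:
    """Subsample each cell's UMIs without replacement to exactly
    ``target``; cells at or below the target are unchanged."""
    if target < 1:
        raise ValueError("target must be >= 1")
    rng = np.random.default_rng(seed)
    X = counts.X.toarray()
    lib = X.sum(axis=1)
    for i in np.flatnonzero(lib > target):
        X[i] = rng.multivariate_hypergeometric(X[i], target)
    return CountMatrix(sp.csr_matrix(X), counts.cells, counts.genes)


def rank_sum_quality_degs(counts_high: CountMatrix,
                          counts_low: CountMatrix) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum per gene on raw (downsampled) counts
    between quality groups, BH-adjusted across genes."""
    if not counts_high.genes.equals(counts_low.genes):
        raise ValueError("gene universes differ between groups")
    A = counts_high.X.toarray()
    B = counts_low.X.toarray()
    res = stats.mannwhitneyu(A, B, axis=0, alternative="two-sided",
                             method="asymptotic")
    p = np.asarray(res.pvalue, dtype=float)
    # genes identical (all tied) in both groups: define p = 1
    tied = (A.max(axis=0) == A.min(axis=0)) & (B.max(axis=0) == B.min(axis=0)) \
        & (A.max(axis=0) == B.max(axis=0))
    p[tied] = 1.0
    fdr = multipletests(p, method="fdr_bh")[1]
    mean_h, mean_l = A.mean(axis=0), B.mean(axis=0)
    return pd.DataFrame({
        "gene": counts_high.genes, "p": p, "fdr": fdr,
        "mean_high": mean_h, "mean_low": mean_l,
    }).set_index("gene")
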