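"""Graph community clustering with stability checks and marker detection.

Clustering follows the shared-neighbor recipe: the directed kNN graph
is re-weighted by the Jaccard similarity of the two endpoints' neighbor
sets, and modularity is maximized on the resulting undirected graph by
a Louvain-type algorithm (Leiden with the modularity objective),
deterministic given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score, pair_confusion_matrix
from statsmodels.stats.multitest import multipletests

from .containers import NeighborGraph, NormMatrix


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    n_clusters: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("cluster ids must be contiguous from 0")
        self.n_clusters = len(uniq)


def jaccard_edges(graph: NeighborGraph) -> tuple[np.ndarray, np.ndarray]:
    """Jaccard similarity of neighbor sets for every directed kNN edge.

    Two cells sharing all k neighbors get weight 1.  Returned as
    (edges[m, 2], weights[m]) over unique undirected pairs.
    """
    idx = graph.indices
    n, k = idx.shape
    neighbor_sets = [set(row) for row in idx]
    pairs = {}
    for i in range(n):
        for j in idx[i]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            if (a, b) in pairs:
                continue
            inter = len(neighbor_sets[a] & neighbor_sets[b])
            union = len(neighbor_sets[a] | neighbor_sets[b])
            pairs[(a, b)] = inter / union if union else 0.0
    edges = np.array(list(pairs.keys()), dtype=int)
    weights = np.array(list(pairs.values()))
    return edges, weights


def community_detect(graph: NeighborGraph, seed: int = 0) -> ClusterAssignment:
    """Modularity communities on the Jaccard-weighted shared-neighbor graph."""
    n = graph.n_cells
    if n == 0:
        raise ValueError("empty graph")
    edges, weights = jaccard_edges(graph)
    keep = weights > 0
    g = igraph.Graph(n=n, edges=[tuple(e) for e in edges[keep]])
    part = leidenalg.find_partition(
        g, leidenalg.ModularityVertexPartition,
        weights=list(weights[keep]), seed=seed, n_iterations=-1)
    labels = np.asarray(part.membership, dtype=int)
    # re-id clusters by decreasing size, ties by first occurrence
    sizes = np.bincount(labels)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(len(order))
    return ClusterAssignment(remap[labels], len(sizes),
                             params={"k": graph.k, "seed": seed})


def rand_index(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Plain Rand index via pair counting."""
    (tn, fp), (fn, tp) = pair_confusion_matrix(labels_a, labels_b)
    total = tn + fp + fn + tp
    return float((tp + tn) / total) if total else 1.0


def rand_index_stability(embedding, k: int = 30, deltas: tuple[int, ...] = (5, 10),
                         threshold: float = 0.8, seed: int = 0) -> pd.DataFrame:
    """Cluster at k and k +/- delta and report pairwise (adjusted) Rand
    indices against the reference k; ``passed`` iff all plain RI exceed
    the threshold."""
    from .preprocess import knn_graph

    X = embedding.values if hasattr(embedding, "values") else np.asarray(embedding)
    n = X.shape[0]
    ref = community_detect(knn_graph(X, k=k), seed=seed)
    rows = []
    for delta in deltas:
        for k2 in (k - delta, k + delta):
            if k2 < 2 or k2 >= n:
                continue
            other = community_detect(knn_graph(X, k=k2), seed=seed)
            rows.append({
                "k_ref": k, "k_alt": k2, "delta": delta,
                "rand_index": rand_index(ref.labels, other.labels),
                "adjusted_rand_index": adjusted_rand_score(ref.labels,
                                                           other.labels),
            })
    out = pd.DataFrame(rows)
    out.attrs["passed"] = bool((out["rand_index"] > threshold).all())
    return out


def rank_sum_markers(norm: NormMatrix, clusters: ClusterAssignment) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum markers per cluster.

    BH correction is applied across genes within each cluster; log2
    fold-change of group means (pseudocount 1e-9) is reported.
    """
    if clusters.n_clusters < 2:
        raise ValueError("need at least 2 clusters for marker detection")
    X = norm.X
    frames = []
    for cid in range(clusters.n_clusters):
        mask = clusters.labels == cid
        if mask.sum() < 2:
            warnings.warn(f"cluster {cid} is a singleton; skipped")
            continue
        res = stats.mannwhitneyu(X[mask], X[~mask], axis=0,
                                 alternative="two-sided", method="asymptotic")
        p = np.asarray(res.pvalue, dtype=float)
        tied = X.max(axis=0) == X.min(axis=0)
        p[tied] = 1.0
        fdr = multipletests(p, method="fdr_bh")[1]
        m_in, m_out = X[mask].mean(axis=0), X[~mask].mean(axis=0)
        lfc = np.log2((m_in + 1e-9) / (m_out + 1e-9))
        frames.append(pd.DataFrame({
            "cluster": cid, "gene": norm.genes, "p": p, "fdr": fdr,
            "log2fc": lfc,
        }))
    return pd.concat(frames, ignore_index=True)
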