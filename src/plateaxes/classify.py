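"""Signature scoring and semi-supervised classification.

Cell populations (here: forebrain, midbrain/r1, hindbrain, midline) are
scored by signed marker-set signatures, a high-confidence training set
is derived from per-type signature-score percentiles, and the remaining
cells are labeled by an absorbing Markov chain on the cell-cell kernel:
training cells are absorbing states and each unlabeled cell takes the
label whose absorbing class a random walk from it reaches with the
highest probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .containers import NeighborGraph, NormMatrix
from .kernels import adaptive_affinity, knn_graph, row_stochastic


@dataclass
class SignatureSet:
    """Positive (and optionally negative) marker genes for one label."""

    name: str
    positive: list[str]
    negative: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.positive:
            raise ValueError(f"signature {self.name!r} has no positive genes")
        neg = set(self.negative or [])
        if neg & set(self.positive):
            raise ValueError(f"signature {self.name!r} has genes in both sets")


def signature_score(norm: NormMatrix, sigset: SignatureSet) -> np.ndarray:
    """Signed signature z-score per cell.

    Two-set case: raw = mean expression over positives minus mean over
    negatives; null variance sigma_c^2 (1/|P| + 1/|N|) where sigma_c^2
    is the cell's all-gene expression variance (a random signature of
    the same sizes).  One-set case: the per-cell all-gene mean replaces
    the negative term and the null variance is sigma_c^2 / |P|.
    Zero-variance cells score 0 by convention.
    """
    missing = [g for g in sigset.positive + (sigset.negative or [])
               if g not in norm.genes]
    if missing:
        raise KeyError(f"signature genes not in universe: {missing}")
    X = norm.X
    mu_c = X.mean(axis=1)
    var_c = X.var(axis=1)
    pos_idx = [norm.genes.get_loc(g) for g in sigset.positive]
    pos_mean = X[:, pos_idx].mean(axis=1)
    n_p = len(pos_idx)
    if sigset.negative:
        neg_idx = [norm.genes.get_loc(g) for g in sigset.negative]
        raw = pos_mean - X[:, neg_idx].mean(axis=1)
        null_var = var_c * (1.0 / n_p + 1.0 / len(neg_idx))
    else:
        raw = pos_mean - mu_c
        null_var = var_c / n_p
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(null_var > 0, raw / np.sqrt(np.maximum(null_var, 1e-300)),
                     0.0)
    return z


def score_table(norm: NormMatrix, sigsets: list[SignatureSet]) -> pd.DataFrame:
    return pd.DataFrame(
        {s.name: signature_score(norm, s) for s in sigsets},
        index=norm.cells)


def build_training_set(scores: pd.DataFrame,
                       prelim_labels: pd.Series,
                       percentile: float = 20.0) -> pd.Series:
    """High-confidence training labels from per-type score percentiles.

    For each type t, the threshold is the ``percentile``-th percentile
    of score_t among cells preliminarily labeled t.  A cell is a
    training example for t iff its t-score exceeds t's threshold and
    every other type's score is at or below that type's threshold.
    Returns a Series with type labels, NaN for unlabeled cells.
    """
    types = list(scores.columns)
    thresholds = {}
    for t in types:
        members = prelim_labels == t
        if members.sum() == 0:
            raise ValueError(f"type {t!r} has no preliminarily labeled cells")
        thresholds[t] = np.percentile(scores.loc[members, t], percentile)
    above = pd.DataFrame({t: scores[t] > thresholds[t] for t in types})
    n_above = above.sum(axis=1)
    training = pd.Series(np.nan, index=scores.index, dtype=object)
    exclusive = n_above == 1
    training[exclusive] = above.loc[exclusive].idxmax(axis=1)
    for t in types:
        if (training == t).sum() == 0:
            raise ValueError(f"type {t!r} has an empty training set")
    return training


def absorb_classify(graph: NeighborGraph, training: pd.Series,
                    ka: int | None = None) -> tuple[pd.Series, pd.DataFrame]:
    """Label propagation by absorbing Markov chain.

    Transition probabilities are row-normalized symmetric adaptive
    Gaussian kernel weights (the diffusion kernel).  Training cells are
    absorbing; absorption probabilities B of unlabeled cells solve
    (I - Q) B = R with absorbing states aggregated by label.  Each
    unlabeled cell is assigned argmax_label B (ties by lexicographic
    label order).  Returns (labels, absorption probability table).
    """
    n = graph.n_cells
    lab_mask = training.notna().to_numpy()
    if lab_mask.sum() == 0:
        raise ValueError("no labeled cells")
    labels = sorted(training.dropna().unique())
    A = graph.weights if graph.weights is not None else adaptive_affinity(graph, ka=ka)
    P = row_stochastic(A)

    unl = np.flatnonzero(~lab_mask)
    lab = np.flatnonzero(lab_mask)
    out = training.copy()
    B_full = pd.DataFrame(0.0, index=training.index, columns=labels)
    for i, lbl in enumerate(labels):
        B_full.loc[training == lbl, lbl] = 1.0
    if unl.size == 0:
        return out, B_full

    Q = P[np.ix_(unl, unl)]
    # aggregate absorbing columns by label
    R_cols = []
    lab_labels = training.iloc[lab].to_numpy()
    P_ul = P[np.ix_(unl, lab)]
    for lbl in labels:
        R_cols.append(np.asarray(
            P_ul[:, lab_labels == lbl].sum(axis=1)).ravel())
    R = np.column_stack(R_cols)
    I_minus_Q = sp.identity(unl.size, format="csc") - sp.csc_matrix(Q)
    try:
        B = spla.spsolve(I_minus_Q, R)
    except Exception as err:  # pragma: no cover - singular systems
        raise ValueError(f"singular absorbing-chain system: {err}") from err
    B = np.atleast_2d(B)
    if B.shape[0] != unl.size:
        B = B.T
    row_sums = B.sum(axis=1)
    if np.any(row_sums < 1e-8):
        bad = unl[row_sums < 1e-8]
        raise ValueError(f"unlabeled cells unreachable from labeled set: {bad[:5]}")
    # argmax with lexicographic tie-break (labels sorted; argmax takes first)
    assigned = [labels[j] for j in np.argmax(B, axis=1)]
    out.iloc[unl] = assigned
    B_full.iloc[unl] = B
    return out, B_full


def classify_regions(norm: NormMatrix, marker_sets: dict[str, list[str]],
                     k: int = 30, percentile: float = 20.0,
                     embedding: np.ndarray | None = None) -> tuple[pd.Series, pd.DataFrame]:
    """End-to-end region classification from marker gene sets.

    Signature scores -> preliminary argmax labels -> percentile training
    set -> absorbing-chain propagation on the expression (or supplied
    embedding) kernel.
    """
    sigsets = [SignatureSet(name, genes) for name, genes in marker_sets.items()]
    scores = score_table(norm, sigsets)
    prelim = scores.idxmax(axis=1)
    training = build_training_set(scores, prelim, percentile=percentile)
    X = embedding if embedding is not None else norm.X
    graph = knn_graph(np.asarray(X, dtype=float), k=min(k, norm.n_cells - 1))
    return absorb_classify(graph, training)
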