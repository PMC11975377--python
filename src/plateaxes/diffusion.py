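"""Diffusion maps with adaptive kernels and eigengap component selection.

The cell-cell Markov chain is built from an adaptive Gaussian kernel on
the kNN graph (bandwidth = distance to the ka-th neighbor), symmetrized
and row-normalized.  Eigenvectors are obtained through the symmetric
conjugate D^(-1/2) A D^(-1/2); the trivial unit eigenvector is dropped
and the remaining components are indexed DC0, DC1, ... in descending
eigenvalue order.  The number of informative components is chosen at
the largest eigengap within the first 40 eigenvalues, and components
can be rescaled by lambda/(1-lambda) into a multiscale embedding whose
Euclidean distances approximate diffusion distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import stats

from .containers import Embedding, NormMatrix
from .kernels import adaptive_affinity, knn_graph, row_stochastic


@dataclass
class MarkovChain:
    """Row-stochastic cell-cell transition matrix with its kernel params."""

    P: sp.csr_matrix
    k: int
    ka: int

    def __post_init__(self) -> None:
        rows = np.asarray(self.P.sum(axis=1)).ravel()
        if not np.allclose(rows, 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1")


@dataclass
class DiffusionResult:
    """Nontrivial diffusion components, eigengap selection and orientation."""

    components: np.ndarray      # cells x m, unit norm, DC0 first
    eigenvalues: np.ndarray     # descending, trivial lambda=1 removed
    n_selected: int
    orientation: dict           # component index -> anchor record

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def selected(self) -> np.ndarray:
        return self.components[:, : self.n_selected]


def diffusion_map(data: NormMatrix | np.ndarray, k: int = 30,
                  ka: int | None = None, n_eigs: int = 41,
                  eigengap_window: int = 40) -> tuple[MarkovChain, DiffusionResult]:
    """Compute the diffusion map of a cell population.

    ``data`` is the log-normalized expression matrix (or any embedding);
    distances are Euclidean in that space.
    """
    X = data.X if isinstance(data, NormMatrix) else np.asarray(data, float)
    n = X.shape[0]
    if ka is None:
        ka = max(1, k // 3)
    graph = knn_graph(X, k=k)
    A = adaptive_affinity(graph, ka=ka)
    d = np.asarray(A.sum(axis=1)).ravel()
    if np.any(d <= 0):
        raise ValueError("isolated cells in the affinity graph")
    P = row_stochastic(A)

    d_isqrt = 1.0 / np.sqrt(d)
    M = sp.diags(d_isqrt) @ A @ sp.diags(d_isqrt)
    M = (M + M.T) * 0.5  # exact symmetry for the solver
    n_eigs = min(n_eigs, n - 1)
    # deterministic Lanczos start vector; ARPACK otherwise randomizes
    v0 = np.full(n, 1.0 / np.sqrt(n))
    vals, vecs = spla.eigsh(M, k=n_eigs, which="LA", v0=v0)
    order = np.argsort(-vals)
    vals, vecs = vals[order], vecs[:, order]

    if n_eigs > 1 and vals[1] > 1 - 1e-10:
        raise ValueError(
            "eigenvalue 1 has multiplicity > 1: the graph is disconnected; "
            "subset to connected components before computing diffusion maps"
        )
    # back-transform to right eigenvectors of P, drop the trivial one
    psi = vecs * d_isqrt[:, None]
    psi = psi / np.linalg.norm(psi, axis=0, keepdims=True)
    # canonical sign: the entry of largest magnitude is positive
    extreme = np.argmax(np.abs(psi), axis=0)
    signs = np.sign(psi[extreme, np.arange(psi.shape[1])])
    signs[signs == 0] = 1.0
    psi = psi * signs
    comp, lam = psi[:, 1:], vals[1:]
    n_selected = eigengap_select(lam, window=eigengap_window)
    return (MarkovChain(P=P, k=k, ka=ka),
            DiffusionResult(components=comp, eigenvalues=lam,
                            n_selected=n_selected, orientation={}))


def eigengap_select(eigenvalues: np.ndarray, window: int = 40) -> int:
    """Number of components preceding the largest eigengap within the
    first ``window`` nontrivial eigenvalues."""
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 3:
        raise ValueError("need at least 3 nontrivial eigenvalues")
    if lam.size < window:
        warnings.warn(f"only {lam.size} eigenvalues available; "
                      f"shrinking the eigengap window from {window}")
        window = lam.size
    gaps = lam[: window - 1] - lam[1:window]
    return int(np.argmax(gaps)) + 1


def multiscale_embed(result: DiffusionResult, cells=None,
                     n_components: int | None = None) -> Embedding:
    """Rescale components by lambda/(1-lambda) (multiscale space)."""
    m = result.n_selected if n_components is None else n_components
    lam = result.eigenvalues[:m]
    if np.any(lam >= 1 - 1e-12):
        raise ValueError("eigenvalue at 1 among selected components "
                         "(disconnected graph)")
    scale = lam / (1.0 - lam)
    import pandas as pd
    if cells is None:
        cells = pd.RangeIndex(result.components.shape[0])
    return Embedding(result.components[:, :m] * scale[None, :],
                     kind="multiscale", cells=cells,
                     eigenvalues=lam.copy())


def annotate_component(result: DiffusionResult, norm: NormMatrix,
                       component: int, n_top: int = 100,
                       p_cutoff: float = 0.01):
    """Genes most correlated with one diffusion component.

    Pearson r of each gene with the component, two-sided p from the
    t-transform; returns up to ``n_top`` significant genes per sign,
    ranked by |r|.
    """
    import pandas as pd
    dc = result.components[:, component]
    X = norm.X
    n = X.shape[0]
    xc = dc - dc.mean()
    Xc = X - X.mean(axis=0, keepdims=True)
    num = Xc.T @ xc
    denom = np.sqrt((Xc**2).sum(axis=0) * (xc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(denom > 0, p, 1.0)
    tab = pd.DataFrame({"gene": norm.genes, "r": r, "p": p})
    sig = tab[tab["p"] < p_cutoff]
    pos = sig[sig["r"] > 0].nlargest(n_top, "r")
    neg = sig[sig["r"] < 0].nsmallest(n_top, "r")
    out = pd.concat([pos.assign(sign="positive"), neg.assign(sign="negative")])
    return out.reindex(out["r"].abs().sort_values(ascending=False).index)


def orient_component(result: DiffusionResult, component: int,
                     anchor: str | list[str], norm: NormMatrix) -> DiffusionResult:
    """Flip a component's sign so the anchor gene (set) correlates
    positively with it; idempotent and logged in ``result.orientation``."""
    anchors = [anchor] if isinstance(anchor, str) else list(anchor)
    expr = np.column_stack([norm.gene_vector(a) for a in anchors]).mean(axis=1)
    dc = result.components[:, component]
    r = np.corrcoef(expr, dc)[0, 1]
    if np.isnan(r) or r == 0:
        warnings.warn(f"anchor {anchors} uncorrelated with component "
                      f"{component}; keeping sign")
        flipped = False
    else:
        flipped = r < 0
        if flipped:
            result.components[:, component] = -dc
    result.orientation[component] = {"anchor": anchors, "r": float(abs(r)) if not np.isnan(r) else 0.0,
                                     "flipped": bool(flipped)}
    return result
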