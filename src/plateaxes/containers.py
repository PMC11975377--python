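"""Shared in-memory containers for the pipeline.

The pipeline's primary object is a cells x genes UMI count matrix held
sparse (CSR), with cell and gene identifiers attached.  Derived objects
(normalized matrices, embeddings, neighbor graphs) are thin dataclasses
so every stage has an explicit, serializable contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class CountMatrix:
    """Raw cells x genes UMI counts (sparse), the pipeline's primary input."""

    X: sp.csr_matrix
    cells: pd.Index
    genes: pd.Index

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.cells = pd.Index(self.cells, name="cell")
        self.genes = pd.Index(self.genes, name="gene")
        if self.X.shape != (len(self.cells), len(self.genes)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.cells)} cells x {len(self.genes)} genes"
            )
        if self.genes.has_duplicates:
            raise ValueError("duplicate gene identifiers")

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(self.X[idx], self.cells[idx], self.genes)

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=1)).ravel()


@dataclass
class NormMatrix:
    """Median-library-size normalized, log1p expression (cells x genes).

    ``provenance`` records the transforms applied, in order, so any
    table written downstream can state exactly what its values are.
    """

    X: np.ndarray
    cells: pd.Index
    genes: pd.Index
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.cells = pd.Index(self.cells, name="cell")
        self.genes = pd.Index(self.genes, name="gene")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("normalized matrix contains non-finite values")

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    def gene_vector(self, gene: str) -> np.ndarray:
        return self.X[:, self.genes.get_loc(gene)]

    def subset_cells(self, mask_or_idx) -> "NormMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NormMatrix(self.X[idx], self.cells[idx], self.genes,
                          list(self.provenance))


@dataclass
class Embedding:
    """Cells x components real matrix (PCA / diffusion / multiscale)."""

    values: np.ndarray
    kind: str  # pca | diffusion | multiscale
    cells: pd.Index
    eigenvalues: np.ndarray | None = None       # diffusion only
    variance_explained: np.ndarray | None = None  # pca only

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("embedding must be 2-D with >= 1 component")

    @property
    def n_components(self) -> int:
        return self.values.shape[1]


@dataclass
class NeighborGraph:
    """Directed kNN graph over cells: indices/distances plus optional
    symmetric kernel weights (used by diffusion, classification and
    autocorrelation)."""

    indices: np.ndarray    # (n, k) neighbor indices, self excluded
    distances: np.ndarray  # (n, k) matching distances
    k: int
    weights: sp.csr_matrix | None = None  # symmetric, zero diagonal

    @property
    def n_cells(self) -> int:
        return self.indices.shape[0]

    def edge_list(self) -> pd.DataFrame:
        n, k = self.indices.shape
        return pd.DataFrame({
            "src": np.repeat(np.arange(n), k),
            "dst": self.indices.ravel(),
            "distance": self.distances.ravel(),
        })
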