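"""Reading and writing the pipeline's on-disk formats.

Counts travel as a Matrix Market triplet (matrix.mtx, 1-based on disk
per the standard, cells as rows) with genes.tsv / barcodes.tsv, or as
a dense CSV (cells x genes, first column = cell id).  All other tables
are plain CSV; configuration is YAML.  Indices are 0-based in memory
and in CSV outputs.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .containers import CountMatrix


def read_counts(path: str, raw: bool = True) -> CountMatrix:
    """Load counts from an MTX triplet directory or a dense CSV file."""
    if os.path.isdir(path):
        mtx = os.path.join(path, "matrix.mtx")
        if not os.path.exists(mtx):
            raise FileNotFoundError(f"no matrix.mtx under {path}")
        X = sp.csr_matrix(scipy.io.mmread(mtx))
        genes = pd.read_csv(os.path.join(path, "genes.tsv"), sep="\t",
                            header=None)[0]
        cells = pd.read_csv(os.path.join(path, "barcodes.tsv"), sep="\t",
                            header=None)[0]
    elif path.endswith(".csv"):
        df = pd.read_csv(path, index_col=0)
        X = sp.csr_matrix(df.to_numpy())
        genes = pd.Index(df.columns)
        cells = pd.Index(df.index.astype(str))
    else:
        raise ValueError(f"unrecognized counts input: {path}")
    if X.shape[0] != len(cells):
        raise ValueError(
            f"barcode count ({len(cells)}) != matrix rows ({X.shape[0]})")
    if X.shape[1] != len(genes):
        raise ValueError(
            f"gene count ({len(genes)}) != matrix columns ({X.shape[1]})")
    if raw:
        data = X.data
        if data.size and not np.allclose(data, np.round(data)):
            raise ValueError("non-integer values in raw count matrix")
        X = X.astype(np.int64)
    return CountMatrix(X, cells, genes)


def write_counts(counts: CountMatrix, path: str, field: str = "integer") -> None:
    """Write the MTX triplet for a count (or real-valued) matrix."""
    os.makedirs(path, exist_ok=True)
    scipy.io.mmwrite(os.path.join(path, "matrix.mtx"),
                     sp.coo_matrix(counts.X), field=field)
    pd.Series(counts.genes).to_csv(os.path.join(path, "genes.tsv"),
                                   sep="\t", index=False, header=False)
    pd.Series(counts.cells).to_csv(os.path.join(path, "barcodes.tsv"),
                                   sep="\t", index=False, header=False)


def load_yaml(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def dump_json(obj, path: str) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
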