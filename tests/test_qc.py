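"""QC cascade: metric oracles, strict boundary rules, bimodal split,
cluster reassignment, downsampling and the rank-sum DE screen."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from plateaxes.containers import CountMatrix
from plateaxes.qc import (compute_cell_metrics, downsample_counts,
                          fit_complexity_model, rank_sum_quality_degs,
                          run_qc, split_bimodal_library, threshold_filter)


def make_counts(X, genes=None):
    X = np.asarray(X)
    genes = genes or [f"g{i}" for i in range(X.shape[1])]
    cells = [f"c{i}" for i in range(X.shape[0])]
    return CountMatrix(sp.csr_matrix(X), cells, genes)


def test_metrics_toy_and_degenerate():
    cm = make_counts([[5, 5], [0, 0]], genes=["mt-a", "b"])
    m = compute_cell_metrics(cm)
    assert m.loc["c0", "library_size"] == 10
    assert m.loc["c0", "n_genes"] == 2
    assert m.loc["c0", "mito_frac"] == 0.5
    # all-zero cell: mito fraction defined as 0
    assert m.loc["c1", "library_size"] == 0
    assert m.loc["c1", "mito_frac"] == 0.0


def test_metrics_match_dense_oracle(default_sim):
    counts, _ = default_sim
    m = compute_cell_metrics(counts)
    X = counts.X.toarray()
    mito = np.asarray(counts.genes.str.startswith("mt-"))
    assert np.array_equal(m["library_size"], X.sum(axis=1))
    assert np.array_equal(m["n_genes"], (X > 0).sum(axis=1))
    lib = X.sum(axis=1)
    expected = np.where(lib > 0, X[:, mito].sum(axis=1) / np.maximum(lib, 1), 0)
    assert np.allclose(m["mito_frac"], expected)
    # library_size >= n_genes since each expressed gene has >= 1 UMI
    assert (m["library_size"] >= m["n_genes"]).all()


def test_threshold_filter_strict_boundaries():
    """Library exactly 1000 and mito exactly 20% are removed (strict
    inequalities)."""
    rng = np.random.default_rng(0)
    n = 40
    X = rng.poisson(10, size=(n, 60))
    X[:, 0] = 0  # reserve the mito gene
    lib = X.sum(axis=1)
    # scale rows to exact libraries
    base = np.full(n, 5000)
    base[0] = 1000   # boundary library
    base[1] = 1001
    counts = np.zeros_like(X)
    for i in range(n):
        counts[i] = rng.multinomial(base[i], X[i] / lib[i])
    # cell 2: mito exactly 20%
    counts[2, 0] = 0
    rest = counts[2, 1:].sum()
    counts[2, 0] = rest // 4  # mito = rest/4 -> frac = 1/5 exactly
    cm = make_counts(counts, genes=["mt-0"] + [f"g{i}" for i in range(59)])
    m = fit_complexity_model(compute_cell_metrics(cm))
    m.loc[:, "complexity_keep"] = True  # isolate the hard filters
    kept = threshold_filter(m)
    assert "c0" not in kept          # library == 1000 removed
    assert "c1" in kept              # library 1001 kept
    mito_frac = m.loc["c2", "mito_frac"]
    assert mito_frac == pytest.approx(0.2)
    assert "c2" not in kept          # mito == 0.20 removed


def test_complexity_residuals_match_ols_oracle(rng):
    n = 200
    lib = 10 ** rng.uniform(3, 4.5, n)
    ngene = 10 ** (0.8 * np.log10(lib) + 0.1 + rng.normal(0, 0.02, n))
    m = pd.DataFrame({"library_size": lib.astype(int),
                      "n_genes": np.maximum(ngene.astype(int), 1)})
    out = fit_complexity_model(m)
    x = np.log10(out["library_size"].to_numpy(dtype=float))
    y = np.log10(out["n_genes"].to_numpy(dtype=float))
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)   # normal-equations oracle
    resid = y - X @ beta
    assert np.allclose(out["complexity_residual"], resid, atol=1e-10)


def test_cells_on_fitted_line_all_kept():
    lib = np.array([1000, 2000, 4000, 8000, 16000] * 4)
    ngene = (lib ** 0.8).astype(int)  # exactly on a power law
    m = pd.DataFrame({"library_size": lib, "n_genes": ngene})
    out = fit_complexity_model(m)
    assert out["complexity_keep"].all()
    # one cell 10x fewer genes than predicted -> residual -1, removed
    m2 = m.copy()
    m2.loc[0, "n_genes"] = max(1, ngene[0] // 10)
    out2 = fit_complexity_model(m2)
    assert out2["complexity_residual"].iloc[0] < -0.5
    assert not out2["complexity_keep"].iloc[0]


def test_bimodal_split_recovers_mixture(rng):
    lib = np.concatenate([10 ** rng.normal(3.0, 0.1, 500),
                          10 ** rng.normal(4.5, 0.1, 500)])
    m = pd.DataFrame({"library_size": lib.astype(int)})
    split = split_bimodal_library(m)
    assert split.antimode is not None
    assert 3.3 < split.antimode < 4.2
    truth = np.array(["low"] * 500 + ["high"] * 500)
    assert (split.assignment.to_numpy() == truth).mean() >= 0.99


def test_bimodal_split_unimodal_fallback_and_permutation_invariance(rng):
    lib = 10 ** rng.normal(3.8, 0.15, 400)
    m = pd.DataFrame({"library_size": lib.astype(int)})
    split = split_bimodal_library(m)
    assert split.antimode is None
    assert (split.assignment == "high").all()
    # permutation invariance on a bimodal sample
    lib2 = np.concatenate([10 ** rng.normal(3.0, 0.1, 300),
                           10 ** rng.normal(4.5, 0.1, 300)])
    m2 = pd.DataFrame({"library_size": lib2.astype(int)})
    perm = rng.permutation(600)
    m2p = m2.iloc[perm].reset_index(drop=True)
    a = split_bimodal_library(m2).assignment.to_numpy()[perm]
    b = split_bimodal_library(m2p).assignment.to_numpy()
    assert np.array_equal(a, b)


def test_full_qc_recovers_injected_cells(lowq_sim):
    """>= 95% of injected low-quality cells removed, <= 2% false
    removals, and cluster labels are per-cluster constant."""
    counts, truth = lowq_sim
    metrics = run_qc(counts)
    low = (truth.cells["quality"] == "low").to_numpy()
    removed = ~metrics["kept"].to_numpy()
    assert (removed & low).sum() / low.sum() >= 0.95
    assert (removed & ~low).sum() / (~low).sum() <= 0.02


def test_qc_filters_are_idempotent(lowq_sim):
    counts, _ = lowq_sim
    metrics = run_qc(counts)
    kept = counts.subset_cells(metrics["kept"].to_numpy())
    metrics2 = run_qc(kept)
    assert metrics2["kept"].all()


def test_downsample_conserves_target_exactly(rng):
    X = rng.poisson(5, size=(30, 50))
    cm = make_counts(X)
    out = downsample_counts(cm, target=100, seed=0)
    lib_in = cm.library_sizes()
    lib_out = out.library_sizes()
    assert np.all(lib_out[lib_in > 100] == 100)
    assert np.all(lib_out[lib_in <= 100] == lib_in[lib_in <= 100])
    assert np.all(out.X.toarray() <= cm.X.toarray())
    # no-op when target >= max library
    same = downsample_counts(cm, target=int(lib_in.max()), seed=0)
    assert (same.X != cm.X).nnz == 0


def test_downsample_matches_hypergeometric_moments():
    """Mean post-downsampling count over many seeds equals the
    hypergeometric expectation target * k_g / N."""
    row = np.array([[60, 30, 10, 0]])
    cm = make_counts(row)
    target = 50
    reps = 1000
    acc = np.zeros(4)
    for s in range(reps):
        acc += downsample_counts(cm, target, seed=s).X.toarray()[0]
    mean = acc / reps
    expected = target * row[0] / row.sum()
    var = (target * (row[0] / row.sum()) * (1 - row[0] / row.sum())
           * (row.sum() - target) / (row.sum() - 1))
    se = np.sqrt(var / reps)
    assert np.all(np.abs(mean - expected) <= 3 * np.maximum(se, 1e-9))


def test_rank_sum_statistic_matches_exhaustive_ranks():
    """10-cell toy: p-value agrees with brute-force rank computation."""
    a = np.array([[1], [3], [5], [7], [9]])
    b = np.array([[2], [4], [6], [8], [20]])
    cm_a, cm_b = make_counts(a), make_counts(b)
    out = rank_sum_quality_degs(cm_a, cm_b)
    pooled = np.concatenate([a.ravel(), b.ravel()])
    ranks = stats.rankdata(pooled)
    U = ranks[:5].sum() - 5 * 6 / 2     # brute-force U for group A
    mu, sd = 5 * 5 / 2, np.sqrt(5 * 5 * 11 / 12)
    z = (U + 0.5 - mu) / sd             # continuity-corrected, U < mu
    p_oracle = 2 * stats.norm.cdf(z)
    assert out["p"].iloc[0] == pytest.approx(p_oracle, rel=1e-6)


def test_rank_sum_null_and_extreme_separation(rng):
    X = rng.poisson(3, size=(200, 300))
    cm_a = make_counts(X[:100])
    cm_b = make_counts(X[100:])
    out = rank_sum_quality_degs(cm_a, cm_b)
    assert (out["fdr"] < 0.05).mean() <= 0.05
    # gene expressed only in the low group ranks among the smallest p
    X2 = X.copy()
    X2[:100, 0] = 0
    X2[100:, 0] = rng.poisson(5, 100) + 1
    out2 = rank_sum_quality_degs(make_counts(X2[:100]), make_counts(X2[100:]))
    assert out2["p"].iloc[0] <= out2["p"].quantile(0.01)


def test_all_tied_gene_gets_p_one():
    X = np.ones((10, 2), dtype=int)
    out = rank_sum_quality_degs(make_counts(X[:5]), make_counts(X[5:]))
    assert out["p"].iloc[0] == 1.0
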