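"""Region-wise two-condition differential expression (hurdle test).

Droplet scRNA-seq expression is zero-inflated, so each gene is tested
in two parts: a discrete part (Fisher's exact test on the 2x2
detection table) and a continuous part (Welch t-test of
log2(normalized + 1) among detected cells only), combined by Fisher's
method (chi-square, 4 df) when both parts are defined.  The reported
effect size is the difference of group means of log2(normalized + 1)
over all cells (zeros included), an analogue of a hurdle-model
log2 fold-change.  BH correction is applied across genes within each
region; a gene is called if it passes FDR < 0.001 with |effect| > 0.24
in at least one region, and its reported region set is every region
with FDR < 0.001 and |effect| > 0.10.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FDR_CUTOFF = 0.001
PRIMARY_EFFECT = 0.24
REPORT_EFFECT = 0.10


def _log2_normalized(counts: np.ndarray, lib: np.ndarray, median_lib: float) -> np.ndarray:
    return np.log2(1.0 + counts * (median_lib / lib)[:, None])


def hurdle_test(group_a: np.ndarray, group_b: np.ndarray) -> pd.DataFrame:
    """Two-part hurdle test per gene between two groups.

    ``group_a`` / ``group_b``: cells x genes matrices of
    log2(normalized + 1) expression.  Returns per-gene detection rates,
    part p-values, combined p and the all-cells mean-difference effect
    (group A - group B).
    """
    A = np.atleast_2d(np.asarray(group_a, dtype=float))
    B = np.atleast_2d(np.asarray(group_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("gene dimensions differ between groups")
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = A.shape[0], B.shape[0]
    det_a = (A > 0).sum(axis=0)
    det_b = (B > 0).sum(axis=0)

    p_disc = np.ones(A.shape[1])
    for g in range(A.shape[1]):
        if det_a[g] + det_b[g] == 0:
            continue
        table = [[det_a[g], n_a - det_a[g]], [det_b[g], n_b - det_b[g]]]
        p_disc[g] = stats.fisher_exact(table, alternative="two-sided")[1]

    # continuous part on detected cells only; undefined with < 2 per group
    p_cont = np.full(A.shape[1], np.nan)
    for g in np.flatnonzero((det_a >= 2) & (det_b >= 2)):
        xa = A[A[:, g] > 0, g]
        xb = B[B[:, g] > 0, g]
        if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
            p_cont[g] = 1.0 if xa.mean() == xb.mean() else 0.0
            continue
        p_cont[g] = stats.ttest_ind(xa, xb, equal_var=False).pvalue

    undetected = (det_a + det_b) == 0
    p_comb = np.where(
        np.isnan(p_cont), p_disc,
        stats.chi2.sf(-2 * (np.log(np.maximum(p_disc, 1e-300))
                            + np.log(np.maximum(np.nan_to_num(p_cont, nan=1.0),
                                                1e-300))), df=4),
    )
    p_comb = np.where(undetected, 1.0, p_comb)
    effect = A.mean(axis=0) - B.mean(axis=0)
    effect = np.where(undetected, 0.0, effect)
    return pd.DataFrame({
        "rate_a": det_a / n_a, "rate_b": det_b / n_b,
        "p_discrete": p_disc, "p_continuous": p_cont,
        "p_combined": p_comb, "hurdle_effect": effect,
    })


def region_de(norm_log2_by_region: dict[str, tuple[np.ndarray, np.ndarray]],
              genes: pd.Index) -> pd.DataFrame:
    """Hurdle test per region with BH correction within each region.

    ``norm_log2_by_region`` maps region -> (group A cells x genes,
    group B cells x genes) of log2(normalized + 1) values.
    """
    frames = []
    for region, (A, B) in norm_log2_by_region.items():
        tab = hurdle_test(A, B)
        tab["fdr"] = multipletests(tab["p_combined"], method="fdr_bh")[1]
        tab["region"] = region
        tab["gene"] = genes
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def apply_de_thresholds(results: pd.DataFrame,
                        primary_effect: float = PRIMARY_EFFECT,
                        report_effect: float = REPORT_EFFECT,
                        fdr: float = FDR_CUTOFF) -> pd.DataFrame:
    """Gene/region reporting rule.

    A gene passes the primary rule iff FDR < ``fdr`` and |effect| >
    ``primary_effect`` (strict) in at least one region; its reported
    rows are all regions with FDR < ``fdr`` and |effect| >
    ``report_effect``.
    """
    r = results.copy()
    r["pass_primary_region"] = ((r["fdr"] < fdr)
                                & (r["hurdle_effect"].abs() > primary_effect))
    r["pass_report_region"] = ((r["fdr"] < fdr)
                               & (r["hurdle_effect"].abs() > report_effect))
    primary_genes = set(r.loc[r["pass_primary_region"], "gene"])
    reported = r[r["gene"].isin(primary_genes) & r["pass_report_region"]]
    return reported.reset_index(drop=True)
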