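"""End-to-end orchestration of the axis-reconstruction analyses.

``run_pipeline`` strings the stages into the three analyses the
package exists for:

* temporal — per-region diffusion maps whose top component (DC0)
  orders cells in developmental time; gene trends along it, clustered;
* spatial — a pooled late-stage diffusion map whose components order
  cells along the anterior-posterior (DC0) and mediolateral axes;
  spatially informative genes selected by local autocorrelation on
  single-component and multiscale latents; trends and trend clusters
  per axis;
* modules — multi-resolution Ward modules of the spatially informative
  genes, with a knee-point working cut and named coarser/finer cuts.

Every stage writes plain-text tables under the run directory and the
run report JSON echoes every parameter actually applied, so a run is
reproducible byte for byte from its report.
"""

from __future__ import annotations

import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import autocorr as ac
from . import classify as cl
from . import clustering as cg
from . import de as de_mod
from . import diffusion as dm
from . import io as pio
from . import modules as md
from . import preprocess as pp
from . import qc as qcm
from . import simulate as sim
from . import trends as tr

log = logging.getLogger("plateaxes")


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    counts_path: str | None = None      # None -> simulate
    seed: int = 0
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    late_stages: tuple[int, ...] = (4, 5)
    regions_temporal: tuple[str, ...] = ("forebrain", "midbrain_r1", "hindbrain")
    # stage parameters (defaults follow the contracted analysis recipe)
    k_qc: int = 8
    k_graph: int = 30
    k_trend_cluster: int = 20
    k_impute: int = 5
    t_impute: int = 3
    n_hvgs: int = 3000
    var_threshold: float = 0.75
    eigengap_window: int = 40
    n_multiscale: int = 10
    z_min: float | None = None          # None -> knee point
    fdr_max: float = 1e-5
    range_min: float = 1.0
    annotate_top: int = 100
    annotate_p: float = 0.01
    n_bins: int = 500
    d_cuts: tuple[float, ...] = (10.0, 6.0, 4.0)
    check_stability: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _spearman(a, b) -> float:
    from scipy.stats import spearmanr
    return float(spearmanr(a, b).statistic)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run report (also written as
    report.json under the run directory)."""
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    handler = logging.FileHandler(os.path.join(out, "run.log"))
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report: dict = {"config": config.to_dict(), "stages": {}}

    try:
        # ---- ingest / simulate -------------------------------------
        if config.counts_path is None:
            cfg = sim.SimConfig(**{**asdict(config.sim), "seed": config.seed})
            counts, truth = sim.simulate_tissue(cfg)
            sim.write_fixture(counts, truth, os.path.join(out, "input"))
            markers = sim.marker_gene_sets(truth)
            stage_col = truth.cells["stage"]
            log.info("simulated %d cells x %d genes", counts.n_cells,
                     counts.n_genes)
        else:
            counts = pio.read_counts(config.counts_path)
            truth = None
            meta_path = os.path.join(config.counts_path, "truth_cells.csv")
            stage_col = None
            if os.path.exists(meta_path):
                meta = pd.read_csv(meta_path, index_col=0)
                if "stage" in meta:
                    stage_col = meta["stage"].reindex(counts.cells)
            markers_path = os.path.join(config.counts_path, "markers.yaml")
            if not os.path.exists(markers_path):
                raise FileNotFoundError(
                    "external runs need a markers.yaml next to the counts")
            markers = pio.load_yaml(markers_path)
        report["stages"]["input"] = {"n_cells": counts.n_cells,
                                     "n_genes": counts.n_genes}

        # ---- qc ----------------------------------------------------
        metrics = qcm.run_qc(counts, k=config.k_qc, seed=config.seed)
        metrics.to_csv(os.path.join(out, "qc_metrics.csv"))
        kept = metrics["kept"].to_numpy()
        counts_f = counts.subset_cells(kept)
        if stage_col is not None:
            stage_col = stage_col[kept]
        report["stages"]["qc"] = {"n_kept": int(kept.sum()),
                                  "n_removed": int((~kept).sum())}
        log.info("qc kept %d / %d cells", kept.sum(), kept.size)

        # ---- preprocess -------------------------------------------
        norm = pp.normalize_median_log1p(counts_f)
        cc_genes = [g for g in norm.genes if g.startswith("cc")]
        if cc_genes:
            cc_score = cl.signature_score(norm, cl.SignatureSet("cellcycle",
                                                                cc_genes))
            norm = pp.regress_out_programs(norm, cc_score[:, None],
                                           ["cellcycle"])
        hvgs = pp.select_hvgs(counts_f, n_top=min(config.n_hvgs,
                                                  counts_f.n_genes))
        with open(os.path.join(out, "hvgs.txt"), "w") as fh:
            fh.write("\n".join(hvgs))
        emb = pp.pca_75(norm, hvgs, var_threshold=config.var_threshold)
        pd.DataFrame(emb.values, index=norm.cells).to_csv(
            os.path.join(out, "pca.csv"))
        graph = pp.knn_graph(emb, k=config.k_graph)
        graph.edge_list().to_csv(os.path.join(out, "knn_edges.csv"),
                                 index=False)
        clusters = cg.community_detect(graph, seed=config.seed)
        pd.DataFrame({"cell": norm.cells, "cluster": clusters.labels}).to_csv(
            os.path.join(out, "clusters.csv"), index=False)
        report["stages"]["preprocess"] = {
            "n_hvgs": len(hvgs), "n_pcs": emb.n_components,
            "n_clusters": clusters.n_clusters,
        }
        if config.check_stability:
            stab = cg.rand_index_stability(emb, k=config.k_graph,
                                           seed=config.seed)
            stab.to_csv(os.path.join(out, "stability.csv"), index=False)
            report["stages"]["preprocess"]["stability_passed"] = \
                bool(stab.attrs["passed"])

        # ---- classification ---------------------------------------
        labels, probs = cl.classify_regions(norm, markers, k=config.k_graph)
        cls = probs.copy()
        cls.insert(0, "label", labels)
        cls.to_csv(os.path.join(out, "classification.csv"))
        report["stages"]["classify"] = {
            "counts": labels.value_counts().to_dict()}
        log.info("classified regions: %s", labels.value_counts().to_dict())

        # ---- temporal analysis per region -------------------------
        temporal = {}
        if stage_col is not None:
            for region in config.regions_temporal:
                mask = (labels == region).to_numpy()
                if mask.sum() < 100:
                    log.warning("region %s too small for temporal analysis",
                                region)
                    continue
                sub = norm.subset_cells(mask)
                _, res = dm.diffusion_map(sub, k=config.k_graph,
                                          eigengap_window=config.eigengap_window)
                dc0 = res.components[:, 0]
                stages_r = np.asarray(stage_col)[mask]
                if np.corrcoef(dc0, stages_r)[0, 1] < 0:
                    dc0 = -dc0
                imput = tr.impute_diffusion(sub, res.components[:, :res.n_selected],
                                            k=config.k_impute, t=config.t_impute)
                tm = tr.fit_gene_trends(imput, dc0, n_bins=config.n_bins)
                tcl = tr.cluster_trends(tm, k=config.k_trend_cluster,
                                        seed=config.seed)
                pd.DataFrame(tm.values, index=tm.genes).to_csv(
                    os.path.join(out, f"trends_time_{region}.csv"))
                pd.DataFrame({"gene": tm.genes,
                              "cluster": tcl.labels}).to_csv(
                    os.path.join(out, f"trend_clusters_time_{region}.csv"),
                    index=False)
                temporal[region] = {
                    "n_cells": int(mask.sum()),
                    "dc0_stage_spearman": _spearman(dc0, stages_r),
                    "n_trend_clusters": tcl.n_clusters,
                }
        report["stages"]["temporal"] = temporal

        # ---- spatial diffusion (pooled late stages) ---------------
        if stage_col is not None:
            late_mask = np.isin(np.asarray(stage_col), config.late_stages)
        else:
            late_mask = np.ones(norm.n_cells, dtype=bool)
        norm_late = norm.subset_cells(late_mask)
        labels_late = labels[late_mask]
        _, res = dm.diffusion_map(norm_late, k=config.k_graph,
                                  eigengap_window=config.eigengap_window)
        # orient DC0 anterior -> posterior with a hindbrain marker
        res = dm.orient_component(res, 0, markers["hindbrain"], norm_late)
        # the ML axis component: the selected non-DC0 component most
        # correlated with the midline signature
        mid_score = cl.signature_score(
            norm_late, cl.SignatureSet("midline", markers["midline"]))
        ml_dc, best = 2, 0.0
        for i in range(1, max(res.n_selected, 3)):
            r = abs(np.corrcoef(res.components[:, i], mid_score)[0, 1])
            if r > best:
                ml_dc, best = i, r
        res = dm.orient_component(res, ml_dc, markers["midline"], norm_late)
        pd.DataFrame(res.components, index=norm_late.cells).to_csv(
            os.path.join(out, "diffusion.csv"))
        pd.Series(res.eigenvalues, name="eigenvalue").to_csv(
            os.path.join(out, "eigenvalues.csv"), index_label="component")
        os.makedirs(os.path.join(out, "annotations"), exist_ok=True)
        for i in range(res.n_selected):
            dm.annotate_component(res, norm_late, i,
                                  n_top=config.annotate_top,
                                  p_cutoff=config.annotate_p).to_csv(
                os.path.join(out, "annotations", f"DC{i}.csv"), index=False)
        report["stages"]["spatial"] = {
            "n_cells": norm_late.n_cells, "n_selected": res.n_selected,
            "ml_component": ml_dc,
            "eigenvalues": [float(v) for v in res.eigenvalues[:10]],
        }

        # ---- autocorrelation gene selection -----------------------
        ms = dm.multiscale_embed(res, cells=norm_late.cells,
                                 n_components=min(config.n_multiscale,
                                                  res.n_components))
        latents = {
            "dc0": res.components[:, [0]],
            f"dc{ml_dc}": res.components[:, [ml_dc]],
            "multiscale": ms.values,
        }
        selections = {}
        for name, lat in latents.items():
            W = ac.neighbor_weights(lat, k=config.k_graph)
            tab = ac.autocorrelation_table(W, norm_late, latent_name=name)
            tab = ac.select_spatial_genes(tab, z_min=config.z_min,
                                          fdr_max=config.fdr_max,
                                          range_min=config.range_min,
                                          use_knee=config.z_min is None)
            tab.to_csv(os.path.join(out, f"autocorr_{name}.csv"))
            selections[name] = tab
            report["stages"].setdefault("autocorr", {})[name] = {
                "z_min": tab.attrs["z_min"],
                "n_selected": int(tab["selected"].sum()),
            }

        # ---- spatial gene trends ----------------------------------
        imput_late = tr.impute_diffusion(norm_late, ms,
                                         k=config.k_impute, t=config.t_impute)
        axis_populations = {
            "dc0": (res.components[:, 0],
                    (labels_late != "midline").to_numpy()),
            f"dc{ml_dc}": (res.components[:, ml_dc],
                           labels_late.isin(["midline", "midbrain_r1"]).to_numpy()),
        }
        for name, (axis_vals, cell_mask) in axis_populations.items():
            genes_sel = list(selections[name].index[selections[name]["selected"]])
            if len(genes_sel) < config.k_trend_cluster + 1:
                log.warning("too few selected genes for %s trends", name)
                continue
            sub = imput_late.subset_cells(cell_mask)
            tm = tr.fit_gene_trends(sub, axis_vals[cell_mask],
                                    genes=genes_sel, n_bins=config.n_bins)
            tcl = tr.cluster_trends(tm, k=config.k_trend_cluster,
                                    seed=config.seed)
            pd.DataFrame(tm.values, index=tm.genes).to_csv(
                os.path.join(out, f"trends_{name}.csv"))
            pd.DataFrame({"gene": tm.genes, "cluster": tcl.labels}).to_csv(
                os.path.join(out, f"trend_clusters_{name}.csv"), index=False)
            report["stages"].setdefault("trends", {})[name] = {
                "n_genes": len(genes_sel), "n_clusters": tcl.n_clusters}

        # ---- gene modules in multiscale space ---------------------
        ms_sel = selections["multiscale"]
        mod_genes = list(ms_sel.index[ms_sel["selected"]])
        if len(mod_genes) >= 3:
            dend = md.correlation_linkage(norm_late, mod_genes)
            pio.dump_json({"linkage": dend.linkage.tolist(),
                           "genes": list(dend.genes)},
                          os.path.join(out, "dendrogram.json"))
            d_star, knee_cut = md.select_cut(dend)
            pd.DataFrame({"gene": dend.genes,
                          "module": knee_cut.labels}).to_csv(
                os.path.join(out, "modules_knee.csv"), index=False)
            for D in config.d_cuts:
                cut = md.cut_modules(dend, D)
                pd.DataFrame({"gene": dend.genes, "module": cut.labels}).to_csv(
                    os.path.join(out, f"modules_D{D:g}.csv"), index=False)
            scores = {}
            for cid in range(knee_cut.n_clusters):
                members = [g for g, l in zip(dend.genes, knee_cut.labels)
                           if l == cid]
                scores[f"module{cid}"] = md.module_score(norm_late, members)
            pd.DataFrame(scores, index=norm_late.cells).to_csv(
                os.path.join(out, "module_scores.csv"))
            report["stages"]["modules"] = {
                "n_genes": len(mod_genes), "D_star": d_star,
                "n_modules_knee": knee_cut.n_clusters,
                "median_within_corr": knee_cut.params["median_within_corr"],
            }

        pio.dump_json(report, os.path.join(out, "report.json"))
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
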