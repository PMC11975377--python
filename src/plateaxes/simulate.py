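"""Synthetic patterned-tissue scRNA-seq generator with full ground truth.

Emulates the structure of a staged cranial neural plate dataset: cells
carry a latent anterior-posterior (AP) coordinate in [0, 1], a
mediolateral (ML) coordinate in [-1, 1] (0 = ventral midline) and a
developmental stage; genes follow archetypal patterns along those axes
(AP step functions over contiguous intervals, ML sigmoids, 2-D
products, monotone temporal trends, a shared cell-cycle program) on top
of negative-binomial counts with log-normal library sizes.  A separate
operation injects a low-quality cell mode (shrunken library, inflated
mitochondrial fraction, stress program) so the QC cascade is
exercisable end to end.

Regions are deterministic functions of (ap, ml): the midline band is
|ml| < 0.05; elsewhere forebrain is ap < 1/3, midbrain/r1 is
1/3 <= ap < 2/3 and hindbrain is ap >= 2/3.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix

# contiguous AP activation intervals; the first three coincide with the
# forebrain / midbrain-r1 / hindbrain bands, the next two with unions of
# adjacent bands, the rest with finer sub-domains (rhombomere analogues)
AP_INTERVALS: list[tuple[float, float]] = [
    (0.0, 1 / 3), (1 / 3, 2 / 3), (2 / 3, 1.0),
    (0.0, 2 / 3), (1 / 3, 1.0),
    (0.0, 1 / 6), (1 / 12, 5 / 12), (1 / 6, 1 / 2),
    (5 / 12, 3 / 4), (7 / 12, 11 / 12), (3 / 4, 1.0),
]

MIDLINE_HALF_WIDTH = 0.05
AP_REGION_EDGES = (1 / 3, 2 / 3)

# gene-id reserves, as fractions of n_genes
MITO_FRAC = 0.01
CELLCYCLE_FRAC = 0.02
STRESS_FRAC = 0.01
MITO_BASELINE_SHARE = 0.05  # share of library from mt- genes in healthy cells


@dataclass
class SimConfig:
    """Configuration of the tissue simulator.

    ``n_cells`` is the number of cells *per stage*.  The patterned-gene
    fractions partition the gene universe; a fixed 1% / 2% / 1% of gene
    ids are additionally reserved for mitochondrial (mt- prefixed),
    cell-cycle and stress genes.  ``amplitude`` is the fold-change of a
    patterned gene's mean between its active and inactive domain;
    ``dispersion`` is the NB inverse-dispersion theta (variance =
    mu + mu^2/theta).  Library sizes are log-normal with parameters
    (``lib_mu``, ``lib_sigma``) on the natural-log scale.
    """

    n_cells: int = 500
    n_stages: int = 6
    n_genes: int = 2000
    frac_ap_patterned: float = 0.15
    frac_ml_patterned: float = 0.15
    frac_2d: float = 0.05
    frac_temporal: float = 0.15
    frac_null: float = 0.50
    amplitude: float = 4.0
    dispersion: float = 2.0
    lib_mu: float = float(np.log(5000.0))
    lib_sigma: float = 0.35
    lowq_frac: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        fracs = (self.frac_ap_patterned, self.frac_ml_patterned, self.frac_2d,
                 self.frac_temporal, self.frac_null)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("gene fractions must lie in [0, 1]")
        if sum(fracs) > 1 + 1e-9:
            raise ValueError("gene fractions sum to more than 1")
        if self.n_cells <= 0 or self.n_genes <= 0 or self.n_stages <= 0:
            raise ValueError("n_cells, n_genes and n_stages must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not 0 <= self.lowq_frac < 1:
            raise ValueError("lowq_frac must lie in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator.

    ``cells``: ap, ml, stage, region, quality, cellcycle score per cell.
    ``genes``: archetype and its parameters per gene.
    """

    cells: pd.DataFrame
    genes: pd.DataFrame
    config: SimConfig = field(default=None)  # type: ignore[assignment]


def assign_region(ap: np.ndarray, ml: np.ndarray) -> np.ndarray:
    """Deterministic region labels from latent coordinates."""
    region = np.where(
        np.asarray(ap) < AP_REGION_EDGES[0], "forebrain",
        np.where(np.asarray(ap) < AP_REGION_EDGES[1], "midbrain_r1", "hindbrain"),
    )
    region = np.where(np.abs(np.asarray(ml)) < MIDLINE_HALF_WIDTH,
                      "midline", region)
    return region


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _ml_profile(abs_ml: np.ndarray, direction: str,
                center: float, width: float) -> np.ndarray:
    """Unit-amplitude sigmoid ML activation.

    'up' genes rise laterally away from the midline, 'down' genes peak
    toward it; per-gene centers and widths emulate nested mediolateral
    domains (floor-plate-sharp through broadly graded).
    """
    if direction == "up":
        return _sigmoid((abs_ml - center) / width)
    return _sigmoid((center - abs_ml) / width)


def _lateral_factor(abs_ml: np.ndarray) -> np.ndarray:
    """AP programs are attenuated in the midline band, mirroring the
    distinct transcriptional state of the ventral midline."""
    return _sigmoid((abs_ml - MIDLINE_HALF_WIDTH) / 0.02)


def _gene_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_genes
    n_mito = max(1, round(MITO_FRAC * n))
    n_cc = max(1, round(CELLCYCLE_FRAC * n))
    n_stress = max(1, round(STRESS_FRAC * n))
    n_ap = round(cfg.frac_ap_patterned * n)
    n_ml = round(cfg.frac_ml_patterned * n)
    n_2d = round(cfg.frac_2d * n)
    n_temp = round(cfg.frac_temporal * n)
    n_null = n - (n_mito + n_cc + n_stress + n_ap + n_ml + n_2d + n_temp)
    if n_null < 0:
        raise ValueError(
            "n_genes too small to host one gene per archetype and reserves"
        )
    if cfg.frac_ap_patterned > 0 and n_ap < len(AP_INTERVALS):
        raise ValueError(
            "n_genes too small: fewer AP-patterned genes than AP archetypes"
        )

    rows: list[dict] = []

    def add(count, archetype, namer, **params):
        for j in range(count):
            rows.append({"gene": namer(j), "archetype": archetype,
                         "ap_lo": np.nan, "ap_hi": np.nan, "ml_dir": "",
                         "ml_center": np.nan, "ml_width": np.nan, **params})

    def ml_params(direction, j):
        # 'down' genes alternate floor-plate-sharp midline markers and
        # broader graded medial domains; 'up' genes tile lateral centers
        if direction == "up":
            return float(rng.uniform(0.3, 0.7)), 0.12
        if j % 2 == 0:
            return MIDLINE_HALF_WIDTH, 0.02
        return float(rng.uniform(0.1, 0.3)), 0.1

    for j in range(n_ap):
        lo, hi = AP_INTERVALS[j % len(AP_INTERVALS)]
        rows.append({"gene": f"ap{j:04d}", "archetype": f"ap_step_{j % len(AP_INTERVALS)}",
                     "ap_lo": lo, "ap_hi": hi, "ml_dir": "",
                     "ml_center": np.nan, "ml_width": np.nan})
    for j in range(n_ml):
        direction = "up" if j % 2 == 0 else "down"
        c, w = ml_params(direction, j // 2)
        rows.append({"gene": f"ml{j:04d}",
                     "archetype": f"ml_gradient_{direction}",
                     "ap_lo": np.nan, "ap_hi": np.nan, "ml_dir": direction,
                     "ml_center": c, "ml_width": w})
    for j in range(n_2d):
        lo, hi = AP_INTERVALS[int(rng.integers(len(AP_INTERVALS)))]
        direction = "up" if rng.random() < 0.5 else "down"
        c, w = ml_params(direction, 1 + int(rng.integers(2)))
        rows.append({"gene": f"td{j:04d}", "archetype": "two_dim",
                     "ap_lo": lo, "ap_hi": hi, "ml_dir": direction,
                     "ml_center": c, "ml_width": w})
    for j in range(n_temp):
        direction = "up" if j % 2 == 0 else "down"
        rows.append({"gene": f"tp{j:04d}",
                     "archetype": f"temporal_{direction}",
                     "ap_lo": np.nan, "ap_hi": np.nan, "ml_dir": direction,
                     "ml_center": np.nan, "ml_width": np.nan})
    add(n_cc, "cellcycle", lambda j: f"cc{j:04d}")
    add(n_stress, "stress", lambda j: f"st{j:04d}")
    add(n_mito, "null", lambda j: f"mt-{j:04d}")
    add(n_null, "null", lambda j: f"nl{j:04d}")

    genes = pd.DataFrame(rows)

    # base relative abundances: broad log-normal for null genes, a
    # narrower moderately-expressed band for patterned genes (marker-like)
    rho = np.exp(rng.normal(0.0, 1.0, size=len(genes)))
    patterned = genes["archetype"].str.startswith(
        ("ap_step", "ml_gradient", "two_dim", "temporal", "cellcycle", "stress")
    ).to_numpy()
    rho[patterned] = np.exp(rng.normal(0.5, 0.5, size=int(patterned.sum())))
    # pin the mitochondrial share of baseline expression
    mito = genes["gene"].str.startswith("mt-").to_numpy()
    non_mito_total = rho[~mito].sum()
    rho[mito] = (MITO_BASELINE_SHARE / (1 - MITO_BASELINE_SHARE)
                 * non_mito_total / mito.sum())
    genes["rho"] = rho
    genes["theta"] = float(cfg.dispersion)
    return genes


def _activation_matrix(genes: pd.DataFrame, cells: pd.DataFrame,
                       amplitude: float, n_stages: int) -> np.ndarray:
    """Cells x genes activation factor f_g(ap, ml, stage) in
    [1, 1 + amplitude]: baseline 1 everywhere, raised by ``amplitude``
    times the unit archetype profile inside the active domain, so
    amplitude = 0 makes every patterned gene exactly null."""
    ap = cells["ap"].to_numpy()
    abs_ml = np.abs(cells["ml"].to_numpy())
    stage = cells["stage"].to_numpy().astype(float)
    cc = cells["cellcycle"].to_numpy()
    mid = (n_stages - 1) / 2.0

    F = np.ones((len(cells), len(genes)))
    arch = genes["archetype"].to_numpy()
    a = amplitude
    for g in range(len(genes)):
        kind = arch[g]
        if kind.startswith("ap_step"):
            lo, hi = genes["ap_lo"].iat[g], genes["ap_hi"].iat[g]
            in_ap = ((ap >= lo) & (ap < hi)) | ((hi == 1.0) & (ap == 1.0))
            F[:, g] += a * in_ap * _lateral_factor(abs_ml)
        elif kind.startswith("ml_gradient"):
            F[:, g] += a * _ml_profile(abs_ml, genes["ml_dir"].iat[g],
                                       genes["ml_center"].iat[g],
                                       genes["ml_width"].iat[g])
        elif kind == "two_dim":
            lo, hi = genes["ap_lo"].iat[g], genes["ap_hi"].iat[g]
            in_ap = ((ap >= lo) & (ap < hi)) | ((hi == 1.0) & (ap == 1.0))
            F[:, g] += a * in_ap * _ml_profile(abs_ml, genes["ml_dir"].iat[g],
                                               genes["ml_center"].iat[g],
                                               genes["ml_width"].iat[g])
        elif kind == "temporal_up":
            F[:, g] += a * _sigmoid((stage - mid) / 0.8)
        elif kind == "temporal_down":
            F[:, g] += a * _sigmoid((mid - stage) / 0.8)
        elif kind == "cellcycle":
            F[:, g] += a * cc
        # stress and null stay at baseline 1
    return F


def simulate_tissue(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Draw a staged, spatially patterned UMI count matrix with truth.

    Counts are NB(mean = L_c * rho_g f_g(cell) / sum_g rho_g f_g(cell),
    theta_g) via the Gamma-Poisson mixture, so expected library sizes
    equal the log-normal draws L_c.  Reproducible given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_total = config.n_cells * config.n_stages

    cells = pd.DataFrame({
        "cell": [f"cell{i:05d}" for i in range(n_total)],
        "ap": rng.uniform(0.0, 1.0, n_total),
        "ml": rng.uniform(-1.0, 1.0, n_total),
        "stage": np.repeat(np.arange(config.n_stages), config.n_cells),
        "cellcycle": rng.uniform(0.0, 1.0, n_total),
    })
    cells["region"] = assign_region(cells["ap"].to_numpy(), cells["ml"].to_numpy())
    cells["quality"] = "high"

    genes = _gene_table(config, rng)
    F = _activation_matrix(genes, cells, config.amplitude, config.n_stages)
    weights = F * genes["rho"].to_numpy()[None, :]
    probs = weights / weights.sum(axis=1, keepdims=True)

    lib = rng.lognormal(config.lib_mu, config.lib_sigma, n_total)
    mean = probs * lib[:, None]
    theta = genes["theta"].to_numpy()[None, :]
    lam = rng.gamma(shape=np.broadcast_to(theta, mean.shape),
                    scale=mean / theta)
    counts = rng.poisson(lam).astype(np.int64)

    cm = CountMatrix(sp.csr_matrix(counts), cells["cell"], genes["gene"])
    truth = SimTruth(cells=cells.set_index("cell"),
                     genes=genes.set_index("gene"), config=config)
    if config.lowq_frac > 0:
        cm, truth = inject_low_quality_cells(cm, truth, config.lowq_frac,
                                             seed=config.seed + 1)
    return cm, truth


def inject_low_quality_cells(counts: CountMatrix, truth: SimTruth,
                             lowq_frac: float, seed: int) -> tuple[CountMatrix, SimTruth]:
    """Convert a random subset of cells into a low-quality mode.

    Selected cells have their library binomially thinned to 5-20% of the
    original, mitochondrial fraction inflated above 20% and a stress
    program switched on; ``truth.cells['quality']`` is updated.
    """
    if not 0 <= lowq_frac < 1:
        raise ValueError("lowq_frac must lie in [0, 1)")
    if lowq_frac == 0:
        return counts, truth
    rng = np.random.default_rng(seed)
    n = counts.n_cells
    n_low = int(round(lowq_frac * n))
    low_idx = rng.choice(n, size=n_low, replace=False)

    X = counts.X.toarray()
    gene_names = counts.genes
    mito_cols = np.flatnonzero(gene_names.str.startswith("mt-"))
    stress_cols = np.flatnonzero(
        truth.genes["archetype"].reindex(gene_names).to_numpy() == "stress"
    )
    for i in low_idx:
        keep = rng.uniform(0.05, 0.2)
        X[i] = rng.binomial(X[i], keep)
        lib = X[i].sum()
        # stress program burst: ~15% of the (shrunken) library
        if stress_cols.size:
            s = max(1, int(round(0.15 * max(lib, 1))))
            X[i, stress_cols] += rng.multinomial(s, np.ones(stress_cols.size) / stress_cols.size)
            lib = X[i].sum()
        # inflate mitochondrial fraction to a target above the QC cutoff
        target = rng.uniform(0.25, 0.5)
        cur_mito = X[i, mito_cols].sum()
        add = int(np.ceil(max(0.0, (target * lib - cur_mito) / (1 - target))))
        if add > 0 and mito_cols.size:
            X[i, mito_cols] += rng.multinomial(add, np.ones(mito_cols.size) / mito_cols.size)

    cells = truth.cells.copy()
    quality = cells["quality"].to_numpy().copy()
    quality[low_idx] = "low"
    cells["quality"] = quality
    new_counts = CountMatrix(sp.csr_matrix(X), counts.cells, counts.genes)
    return new_counts, SimTruth(cells=cells, genes=truth.genes, config=truth.config)


def marker_gene_sets(truth: SimTruth, n_per_region: int = 10) -> dict[str, list[str]]:
    """Planted region marker genes, by construction of the archetypes.

    Forebrain / midbrain-r1 / hindbrain markers are AP-step genes whose
    activation interval coincides with the region band; midline markers
    are ML genes peaking at the midline.
    """
    g = truth.genes
    step = g[g["archetype"].str.startswith("ap_step")]
    out: dict[str, list[str]] = {}
    for region, (lo, hi) in zip(("forebrain", "midbrain_r1", "hindbrain"),
                                AP_INTERVALS[:3]):
        sel = step[(step["ap_lo"] == lo) & (step["ap_hi"] == hi)]
        out[region] = list(sel.index[:n_per_region])
    midline = g[(g["archetype"] == "ml_gradient_down")
                & (g["ml_width"] <= 0.05)]
    out["midline"] = list(midline.index[:n_per_region])
    if any(len(v) == 0 for v in out.values()):
        raise ValueError("simulation too small to provide markers for every region")
    return out


def write_fixture(counts: CountMatrix, truth: SimTruth, path: str) -> None:
    """Write the MTX triplet plus truth tables under ``path``."""
    os.makedirs(path, exist_ok=True)
    scipy.io.mmwrite(os.path.join(path, "matrix.mtx"),
                     sp.coo_matrix(counts.X), field="integer")
    pd.Series(counts.genes).to_csv(os.path.join(path, "genes.tsv"),
                                   sep="\t", index=False, header=False)
    pd.Series(counts.cells).to_csv(os.path.join(path, "barcodes.tsv"),
                                   sep="\t", index=False, header=False)
    truth.cells.to_csv(os.path.join(path, "truth_cells.csv"))
    truth.genes.to_csv(os.path.join(path, "truth_genes.csv"))
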