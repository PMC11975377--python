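# Methods

This note documents the models, parameters and design decisions behind
`plateaxes`, in the order the pipeline runs them, together with what
the synthetic generator does and does not emulate.

## Synthetic patterned tissue

The generator draws cells with latent coordinates — anterior-posterior
position `ap ~ U(0, 1)`, mediolateral position `ml ~ U(-1, 1)` (0 is
the ventral midline), a stage index (6 stages by default, 500 cells
each) and a cell-cycle score — and assigns regions deterministically:
the midline band is `|ml| < 0.05`; otherwise forebrain (`ap < 1/3`),
midbrain/r1 (`1/3 ≤ ap < 2/3`), hindbrain (`ap ≥ 2/3`).

Genes follow one archetype each:

* **AP steps** (15% of genes) — indicator activation over one of 11
  contiguous AP intervals: the three region bands, two unions of
  adjacent bands, and six finer sub-domains with staggered breakpoints
  (rhombomere-scale analogues). Staggering matters: with breakpoints
  at only six positions, the binned AP signal caps the achievable rank
  correlation of any reconstructed axis near 0.90. AP activation is
  attenuated inside the midline band, reflecting the distinct
  transcriptional state of the ventral midline relative to flanking
  tissue.
* **ML sigmoids** (15%) — activation sigmoid in `|ml|` with per-gene
  center and width: "down" genes alternate floor-plate-sharp midline
  profiles (center 0.05, width 0.02; these are the planted midline
  markers) and broader graded medial domains; "up" genes tile lateral
  centers in (0.3, 0.7). The nesting emulates the floor-plate /
  lateral marker hierarchy and is what lets one diffusion component
  order `|ml|` while a sharp marker set defines the midline class.
* **2-D products** (5%) — an AP indicator times an ML sigmoid.
* **Temporal logistics** (15%) — monotone in stage, centered mid-way.
  This fraction is deliberately the largest single patterned class:
  within a region subset the temporal program must dominate residual
  ML variation for the top diffusion component to be the time axis,
  which is the empirical situation in staged embryonic tissue where
  the global developmental shift outweighs within-region patterning.
* **Cell-cycle** (2%), **stress** (1%, silent until low-quality
  injection), **mitochondrial** (1% of ids, `mt-` prefix, pinned to a
  5% baseline library share) and **null** genes (the rest).

Counts are Gamma-Poisson (negative binomial, inverse-dispersion θ = 2)
with per-cell means `L_c · ρ_g f_g(cell) / Σ_g ρ_g f_g(cell)`, so the
expected library equals the log-normal draw `L_c`
(median ≈ 5000 UMIs, σ = 0.35 on the natural-log scale). `f` is
`1 + amplitude · profile` with unit-range profiles, so amplitude 0
makes every patterned gene exactly null and the default amplitude 4
gives a five-fold peak. Patterned genes draw marker-like abundances
(log-normal μ = 0.5, σ = 0.5) — markers in real tissues are seldom the
faintest genes, and the log-range filter of the selection stage would
otherwise exclude them for reasons unrelated to patterning.

Low-quality injection thins a chosen fraction of cells' libraries
binomially to 5–20%, adds a stress-gene burst (~15% of the shrunken
library) and inflates the mitochondrial fraction to 25–50%.

**What the generator does not emulate:** ambient RNA, doublets, batch
effects, gene-gene regulatory correlation beyond shared archetypes,
realistic gene names, or spatially varying cell density. Passing
tests therefore demonstrate correctness of the algorithms under a
clean generative model, not robustness to those artifacts.

## QC cascade

Hard filters are strict, matching their printed form: keep iff library
> 1000 UMIs and mitochondrial fraction < 20%. The complexity filter
regresses log10(genes detected) on log10(library) by OLS and removes
residuals < −0.1 (cells with fewer genes than their depth predicts —
the low-complexity, stressed/one-program phenotype). The KDE split
(Gaussian kernel, Silverman bandwidth, 512-point grid) declares
bimodality only when the density valley between two peaks drops below
80% of the smaller peak, which ignores shoulder wiggles of a unimodal
density. Cluster reassignment clusters cells at k = 8 and Z-tests
each cluster's mean log10 library against the high-mode Gaussian
(SE = sd/√n); a cluster is relabeled low only if p < 1e-10 **and** its
mean is closer, in standardized distance, to the low-mode Gaussian
than to the high-mode one. The second condition is essential: with
clusters of hundreds of cells, SE shrinks enough that any cluster
trivially below the high-mode mean is "significant", and significance
alone would discard entire healthy datasets.

Downsampling to a common depth is exact multivariate hypergeometric
sampling (without replacement); quality-mode DE uses two-sided
Wilcoxon rank-sum with BH correction.

## Normalization, HVGs, PCA, graph

Normalization: `x = ln(1 + m·c/L)` with `m` the median library.
Cell-cycle influence is removed by per-gene OLS on centered program
scores (signed signature scores of the cell-cycle gene set), which
preserves gene means exactly; the original analysis used a factor
model for this step, and the regression keeps its intent (removing
cycle covariance) in a fully specified form. HVG ranking follows the
variance-stabilizing recipe: a lowess trend (span 0.3) of log10
variance on log10 mean, counts standardized by the trend sd and
clipped at √n, genes ranked by clipped variance; mitochondrial,
ribosomal and <10-cell genes are excluded, constant genes rank last,
marker lists can be force-kept. PCA keeps the smallest number of
components reaching 75% cumulative variance, computed over at most
200 components — on noise-dominated count data 75% of total variance
can require hundreds of components, and 200 is the desk-scale cap
(a warning reports when the threshold is not reached). PCA is on
centered, unscaled log-normalized HVG expression. kNN graphs are
Euclidean, self excluded, distance ties broken by ascending cell
index.

## Communities and classification

Community detection re-weights kNN edges by the Jaccard similarity of
the endpoints' neighbor sets and maximizes modularity (Leiden,
seeded, iterated to convergence). A caution documented by
measurement: modularity maximization legitimately subdivides large
blobs on sparse geometric graphs (a 200-cell Gaussian blob at k = 15
splits into several communities with far higher modularity than the
single-blob partition), so cluster counts are finer than "number of
separated groups"; downstream stages only rely on communities
refining the real structure. Stability is reported as plain and
adjusted Rand indices between clusterings at k and k ± 5, 10, with a
pass flag at RI > 0.8.

Signature scores: raw = mean over positive genes − mean over negative
genes (or the cell's all-gene mean when no negatives), z-normalized by
the cell-level null variance `σ_c²(1/|P| + 1/|N|)` (one-set:
`σ_c²/|P|`). The one-set null omits the finite-population correction,
a bias of order |P|/G. Training sets take, per type, cells above
their own type's 20th-percentile score threshold and at or below every
other type's. The absorbing chain uses the shared adaptive-kernel
weights; absorption probabilities solve the sparse system
`(I − Q)B = R` with absorbing columns aggregated by label; ties in the
argmax resolve lexicographically.

## Diffusion maps

Affinities `a_ij = exp(−d_ij²/σ_i²)` on the k = 30 kNN graph with
adaptive bandwidth σ_i = distance to the ka = ⌊k/3⌋-th neighbor;
symmetrized by arithmetic mean; rows normalized. Eigenvectors come
from the symmetric conjugate `D^(−1/2) A D^(−1/2)` (ARPACK with a
fixed start vector and a canonical sign convention — largest-magnitude
entry positive — for byte-level reproducibility), the trivial unit
eigenvector is dropped, and "DC0" is the first nontrivial component.
The number of informative components is the position of the largest
gap among the first 40 nontrivial eigenvalues. Duplicate points fall
back to the smallest positive neighbor distance; a disconnected graph
(unit eigenvalue multiplicity > 1) is an error instructing subsetting.
Diffusion maps run directly on the log-normalized matrix, not on PCA
space. Multiscale space rescales component i by λ_i/(1 − λ_i).
Components are annotated by Pearson correlation with every gene
(t-transform p-values, top 100 at p < 0.01 per sign) and oriented by
flipping signs so an anchor marker correlates positively.

Known limitation, observed across seeds: the largest-eigengap rule is
a step function of the spectrum, and at some seeds it stops before the
ML-correlated component even though that component is present and
strongly correlated with `|ml|`. The pipeline reports whatever the
rule selects.

## Local autocorrelation

For standardized expression x on the symmetric weight matrix W (kernel
weights, per-cell out-weights normalized to 1, symmetrized, zero
diagonal): `H = Σ_{i<j} w_ij x_i x_j`. The null model is
permutation-consistent: standardization forces Σx = 0, hence
`E[x_i x_j] = −1/(n−1)` under label permutation and
`E[H] = −S₀/(n−1)` with `S₀ = Σ_{i<j} w_ij`, while
`Var[H] = Σ_{i<j} w_ij²`. Z = (H − E[H])/√Var, one-sided p (positive
autocorrelation is the signal). The mean correction is a deliberate
refinement of the plain E[H] = 0 null: it is what makes the analytic
Z agree with a 10,000-permutation z-score within 0.3 and keeps the
null-gene Z distribution centered (measured |mean| < 0.01, sd ≈ 0.99
over 2000 null genes at 1000 cells). A permutation oracle ships
alongside the analytic form. Selection excludes genes with
log-expression range ≤ 1, then keeps FDR < 1e-5 (BH across
range-passing genes) and Z above a threshold — fixed at 10 or chosen
by knee point on the sorted Z curve (the default in the pipeline,
appropriate at desk scale where absolute Z values are smaller than at
atlas scale).

## Trends and trend clusters

Diffusion imputation: t = 3 steps of the k = 5 adaptive-kernel Markov
chain on the latent space; imputed values feed trend fitting and
display only — selection statistics and DE always use non-imputed
values. Trends are penalized cubic B-spline regressions (8 interior
knots at component quantiles, second-difference coefficient penalty,
smoothing chosen per gene by GCV over λ ∈ 10^{−4..4}), evaluated at
500 equally spaced bins on the min-max-normalized component. The fit
commutes with per-gene affine transforms and reduces knots with a
warning when cells are scarce. Trend clustering z-normalizes trends,
builds a k = 20 kNN graph under correlation distance (1 − Pearson
across bins) and reuses the community detector; flat trends become
flagged singletons. Region masks follow the analysis design: AP
trends on non-midline cells, ML trends on midline + midbrain/r1
cells; temporal trends per region along that region's DC0, oriented by
stage.

## Gene modules

Each selected gene's feature vector is its row of the gene-gene
Pearson correlation matrix (computed on log-normalized expression,
self-correlation included — a fixed convention keeping distances
deterministic); Ward linkage on Euclidean row distances. The working
cut is chosen on the curve of median (over clusters) mean pairwise
within-cluster correlation versus number of clusters: the knee point
(maximum perpendicular distance to the endpoint chord after min-max
normalization, ties to the smallest index) when the curve saturates
monotonically, or the interior peak when over-splitting visibly
dilutes cohesion (margin 0.02). Candidate counts are capped so the
average module holds ≥ 5 genes; without the cap the median is
eventually dominated by near-perfect two-gene clusters and the curve
jumps to 1. Named coarser/finer cuts at fixed linkage heights
(default D = 10, 6, 4, exposed as parameters; raw Ward heights) give
nested refinements. Modules are scored per cell by the one-set
signature score.

## Differential expression

The two-part hurdle test per gene and region: Fisher's exact test on
the 2×2 detection table, Welch's t on log2(normalized + 1) among
detected cells (undefined below 2 detected per group), combined by
Fisher's method (χ², 4 df) when both parts exist. The reported effect
is the difference of group means of log2(normalized + 1) over all
cells — zeros included — an analogue of a hurdle-model combined
effect on the log2 scale; the named hurdle-model package's
logistic-regression internals (and its CDR covariate) are deliberately
re-specified in this desk-testable form, and numerical agreement with
that package's per-gene p-values is a non-goal. Swapping group labels
negates the effect and preserves p-values exactly. BH runs within
each region independently. Reporting: a gene is called iff it passes
FDR < 0.001 with |effect| > 0.24 (strict) in ≥ 1 region; its reported
region set is every region with FDR < 0.001 and |effect| > 0.10.
Midline cells are excluded from DE. Calibration, measured at 200
label-permutation replicates (150 genes, 120 cells/group): mean
discovery fraction at FDR 0.05 ≈ 5e-4, and no replicate produces a
call at the strict thresholds; power for planted 1.5× effects at 300
cells/group and moderate expression (mean ~2 counts, θ = 2) is ≥ 0.8.

## Problem sizes and determinism

The default study conditions are 3000 cells × 2000 genes (500 cells ×
6 stages), amplitude 4, seed 0; the pooled "late-stage" analogue is
stages 4–5 (1000 cells). The full pipeline runs in well under a
minute on one CPU and is byte-identical across reruns with the same
seed (fixed Lanczos start vectors, canonical eigenvector signs,
seeded community detection, one seeded generator in the simulator).
Calibration studies use 2000 null genes × 1000 cells
(autocorrelation), 200 replicates (DE null), and 10,000 permutations
(autocorrelation oracle). All tables are plain text; no binary state
is written.
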