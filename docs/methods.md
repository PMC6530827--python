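# Methods

`gcnbench` reconstructs gene co-expression networks (GCNs) from a
normalized log-signal expression matrix (genes × conditions), detects
modules, and judges candidate networks by structural and biological
criteria. Because the package is exercised on synthetic compendia with
known ground truth, every stage is scored against a planted answer. This
note records the models, the parameters that matter, and the design
choices that were genuinely open.

## The synthetic compendium

Real bacterial compendia are collections of microarray experiments over
growth conditions, with replicate hybridizations, regulon-driven
co-expression blocks, and assorted contamination. The generator
(`gcnbench.simulate`) emulates this with a hierarchical latent-factor
model. For module *m* with unit-variance activity profile
*f<sub>m</sub>(c)* over conditions *c*, a member gene *g* with loading
*l<sub>g</sub>* ~ U(`loading_range`) is observed in sample *s* of
condition *c* as

    x_gs = b_g + s_f · l_g · f_m(c) + γ · u_g · h(c) + ε_gs

with gene baseline *b<sub>g</sub>* ~ N(8, 1) (log₂-scale microarray
signal), noise ε ~ N(0, `noise_sd`²) i.i.d. per sample, and two forms of
shared structure that real compendia exhibit:

* **Correlated regulator activities.** Module profiles share a
  super-factor at pairwise correlation `factor_correlation`
  (f_m = √c·h′ + √(1−c)·z_m). Bacterial regulon activities are strongly
  coupled through growth rate and stress state; genes answering to
  multiple regulators are the reason regulons scatter over modules.
* **A compendium-wide condition effect.** Every gene (background
  included) responds to a global per-condition trend *h(c)* with its own
  susceptibility *u<sub>g</sub>* ~ U(0, 1), scaled by
  `global_effect_sd` (γ). This emulates growth-phase/batch trends that
  inflate marginal correlations without creating direct associations.

The factor scale *s<sub>f</sub>* is calibrated (mean-field, at the mean
loading and mean susceptibility) so that the expected within-module
Pearson correlation equals `within_module_cor`; tests verify the
empirical mean lands within ±0.05 of the target at 500 conditions.

Contamination: a fraction `frac_noisy_genes` of genes get tenfold
replicate variance; `frac_low_signal` genes are shifted three noise
standard deviations below the 5th-percentile detection floor.
Annotations (`simulate_annotations`) give each planted module one
dedicated term covering `frac_correct` of its genes plus uniform random
background assignments — GO-style flat terms, concentrated in modules.
Gold standards (`simulate_regulatory_network`) grow a directed TF→target
network by out-degree-proportional attachment and then force a few
sigma-factor-like hubs to ≥ 120 targets, yielding the long-tailed
out-degree distribution characteristic of curated regulatory databases.

What the generator does **not** emulate: probe-level microarray effects,
normalization artifacts, non-Gaussian noise, operon read-through, and
condition-specific (rather than global) batch structure. Passing tests
therefore demonstrate correctness of the pipeline's machinery and its
qualitative behavior under realistic correlation structure, not
performance on any particular real compendium.

## Preprocessing

Replicates are collapsed per condition by the **median**. Gene filtering
operationalizes "noisy expression" as the median (across conditions) of
the replicate coefficient of variation, cutoff `cv_max` (default 0.5),
and "low signal" as a median below the global `low_quantile` quantile
(default 0.05). Both defaults are configurable; on the default synthetic
scale (signal ≈ 8, noise sd 1) tenfold variance inflation yields CV
≈ 0.4, so catching planted noisy genes requires either a tuned cutoff
(the tests tune to the 90th CV percentile) or reliance on downstream
association thresholds.

## Reconstruction methods

All five methods consume the same matrix and emit a simple undirected
network; genes left without an edge are excluded, so n_g counts
connected genes and n_e/n_g is comparable across methods. Raising any
threshold only removes edges.

* **Pearson / Spearman** — pairwise correlation (ranks first for
  Spearman), edge iff |r| ≥ `r_threshold`. Unsigned thresholding is the
  default everywhere; a signed mode keeps only positive co-expression.
* **GeneNet-style shrinkage partial correlations** — the correlation
  matrix is shrunk toward the identity with the analytic intensity
  λ* = Σ Var̂(r_ij)/Σ r_ij² (clipped to [0, 1]); partial correlations
  come from the inverse; a two-component mixture
  η₀·f₀(r; κ) + (1−η₀)·U[−1, 1] with null density
  f₀ ∝ (1−r²)^((κ−3)/2) is fitted by maximum likelihood, and the edge
  rule is posterior non-null probability ≥ ω. κ is bounded below by
  ~n − p, the sampling degrees of freedom of unshrunk partial
  correlations — shrinkage only concentrates the null — which keeps the
  fit identified when few pairs are observed. A `omega_on_pcor` flag
  thresholds |pcor| directly instead.
* **SPACE** — sparse partial correlation estimation: minimize
  ½·Σᵢ‖Xᵢ − Σ_{j≠i} ρ_ij √(s_jj/s_ii) X_j‖² + λ·Σ|ρ_ij| by coordinate
  descent over gene pairs, each update pooling the two regressions the
  pair appears in (soft thresholding at λ); residual precisions s_ii are
  refreshed between 3 outer iterations; λ = `lambda_scale`·√(n log p) on
  standardized data, uniform regression weights. The objective is
  asserted non-increasing per sweep; an active-set strategy (full sweep,
  then sweeps over nonzero pairs) keeps p ≈ 150 tractable in seconds.
  Edge iff |ρ̂| ≥ `rho_threshold`.
* **WGCNA-style soft thresholding** — adjacency a_ij = |r_ij|^β
  (unsigned), thresholded at τ; the topological overlap matrix
  TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(kᵢ, k_j) + 1 − a_ij) is returned
  alongside for robustness analysis. Whether to threshold on adjacency
  or TOM was open; adjacency was chosen, TOM exposed.
  `select_soft_power` picks the lowest β whose weighted-degree
  distribution fits the scale-free model at R² ≥ target (argmax
  fallback with a warning); β = 5 with τ = 0.8⁵ is the benchmark
  default, so the WGCNA and Pearson edge sets coincide at |r| = 0.8.

**Threshold scales.** Correlation thresholds (r ≈ 0.8) and
partial-correlation thresholds live on different scales: in a one-factor
module of size *m* with within correlation *r*, the true pairwise
partial correlation is ≈ r/(1 + (m−2)r) — for r = 0.85, m = 6 that is
≈ 0.2. The benchmark therefore prunes SPACE at ρ = 0.06 on the
lasso-shrunk estimate scale; a threshold near 0.7, appropriate for the
real-compendium analyses this package mirrors, would simply empty the
network on desk-scale synthetic data.

## Module detection and modularity

Partitioners: Walk-trap (random-walk distances, t = 4 steps by default,
max-Q cut of the merge sequence), Fast-Greedy, and seeded asynchronous
label propagation — delegated to igraph. Newman modularity
Q = Σ_c [e_c/m − (d_c/2m)²] is computed by the package's own
implementation, unweighted by default, and every returned partition's Q
is verified against it to 1e-12; exhaustive search over all set
partitions of ≤ 8-node graphs bounds the partitioners in tests. Modules
are relabeled in decreasing size ("module 0" is the largest). Modules
below `min_module_size` (default 5) are retained but flagged ineligible
for enrichment. Infomap is not implemented; externally computed
partitions can be loaded from TSV for parity experiments.

## Enrichment and the ψ statistics

Per eligible module and per touched term, a one-sided hypergeometric
tail probability (Fisher's exact test) is computed by log-space
summation, with Benjamini–Hochberg correction within each module
(α = 0.05 default; `none` reproduces raw-p workflows). The universe is
the intersection of the partition's genes and the annotation table —
the conservative choice for a network-restricted test.

Summary statistics: **ψ₁** is the mean number of significant terms per
enriched module (enriched = ≥ 1 significant term). **ψ₂** is the total
number of significant tests divided by the number of modules carrying at
least one annotated term; the printed definition of ψ₂ is ambiguous
about this denominator, so the stricter alternative (enriched modules
only, which algebraically equals ψ₁) is reported as `psi2_literal`
rather than silently chosen.

## Topology and power-law fitting

Structural summaries report density 2n_e/(n_g(n_g−1)), n_e/n_g, average
path length and diameter on the largest connected component (with the
component count reported so nothing is hidden), and hubs — genes with
degree ≥ 5 by the usual convention. Degree distributions are exact
empirical PMFs. The power-law exponent is fitted two ways: the exact
discrete MLE (Hurwitz-zeta likelihood, maximized numerically — the
closed-form continuity-corrected estimator is measurably biased low at
small k_min and only seeds the search) with a KS distance against the
fitted CDF, and a log-log regression over unique degrees with its R².
Both are reported; neither is privileged.

## Benchmarking, screening and ranking

Gold standards are collapsed to undirected graphs (reciprocal pairs
merge). Random edge addition inserts exactly ⌈φ·n_e⌉ new edges between
non-adjacent pairs with endpoint probability proportional to degree —
the degree-product weighting preserves the heavy tail while shifting the
degree CDF rightward; this sampling rule is this package's
interpretation of probabilistic edge addition, flagged as such.
Screening discards candidates by three rules — low modularity
(Q < q_min), very sparse connectivity (n_g < g_min), very high
connectivity (n_e/n_g > ratio_max) — and orders survivors by proximity
of n_e/n_g to the nearest gold-standard ratio. Methods are ranked by
rank-sum over five criteria (significant terms, ψ₁, ψ₂, best-partition
Q, power-law R²), ties broken by ψ₂.

Recovery metrics for synthetic truth: edge precision/recall/F1 against
planted within-module pairs, adjusted Rand index for partitions
(scikit-learn), and regulon projection (coverage and single-module
cohesion per gene set).

## The default synthetic benchmark

`pipeline.BENCHMARK_SIM` fixes the study conditions: 10 modules of 3–8
genes (bacterial regulon scale), 30 background genes, 100 conditions in
duplicate, within-module correlation 0.85, factor correlation 0.75,
global effect 0.8, loadings U(0.5, 1.0), 5% noisy and 5% low-signal
genes. Method thresholds: r = 0.8 (Pearson/Spearman), ω = 0.9 (GeneNet),
β = 5 with τ = 0.8⁵ (WGCNA), ρ = 0.06 with λ-scale 1.0 (SPACE). On these
conditions the pipeline reproduces the qualitative method ordering:
SPACE yields the most enriched modular networks; GeneNet the least
enriched; and at matched edge counts the Pearson network is denser and
less modular than SPACE's — the correlated regulator activities place
between-module correlations inside the thresholded range, where marginal
correlation blurs module boundaries and partial correlation does not.
Problem sizes throughout (p ≈ 100–150 genes, n = 100 conditions, 10–20
seeds per study) were chosen so a full run completes in seconds to
minutes on one CPU while leaving every estimator in its operating
regime.

## Numerical choices and degenerate inputs

Zero-variance genes are skipped with a warning, never NaN edges;
correlations within 1e-12 of ±1 are snapped so exact linear dependence
passes a threshold of 1.0. Singular shrunk correlation matrices raise
with advice to increase the shrinkage floor. SPACE raises a convergence
error carrying the last change if the sweep cap is hit. Power-law fits
on fewer than 10 observations warn (low support); all-equal degrees are
an error. Label propagation is deterministic under its seed; Walk-trap
and Fast-Greedy are deterministic outright. The pipeline fans a single
global seed into per-stage seeds by stable hashing of stage names, and
every output file carries a header comment with tool version, config
hash and seed.

## Known limitations

* GeneNet's mixture on desk-scale synthetic data drives η₀ → 1 and
  yields very sparse networks, unlike the dense GeneNet networks seen on
  real compendia; only the enrichment-ranking claim (GeneNet least
  enriched) is scale-independent.
* The one-factor module model makes large modules nearly invisible to
  partial-correlation methods (true pcor ~ 1/m); this is a property of
  the model, not of the estimators.
* GO-term structure is flat; no ancestor propagation.
* The SPACE penalty uses uniform regression weights; degree-weighted
  variants are not implemented.
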