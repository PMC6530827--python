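# gcnbench

Reconstruction and benchmarking of **gene co-expression networks
(GCNs)** from bacterial expression compendia.

Given a normalized log-signal matrix (genes × conditions), which genes
are co-expressed, how should the network be built, and how do you know
it is any good? This package implements the full comparison workflow a
systems biologist would run: five reconstruction methods — Pearson and
Spearman correlation, GeneNet-style shrinkage partial correlations,
SPACE (sparse partial correlation estimation by joint lasso regression),
and WGCNA-style soft thresholding — followed by module detection
(Walk-trap, Fast-Greedy, label propagation), structural analysis
(density, n_e/n_g, path metrics, hubs, discrete power-law fits to the
degree distribution), per-module gene-set overrepresentation (Fisher's
exact tests with the ψ₁/ψ₂ summary statistics), candidate screening
against regulatory gold standards (RegulonDB/SubtiWiki-style TF→target
exports, with probabilistic random edge addition for structural
comparison), and method ranking. A first-class synthetic-data module
generates compendia with planted regulon-like modules, annotations and
scale-free gold standards, so the whole pipeline is testable against
known ground truth.

## The statistics at the core

* **Association.** Marginal: r (Pearson/Spearman), edge iff |r| ≥ r₀.
  Partial: GeneNet shrinks R toward I with analytic intensity
  λ* = Σ Var̂(r_ij)/Σ r_ij², inverts, and converts partial correlations
  to posterior edge probabilities via a null mixture
  f₀(r; κ) ∝ (1−r²)^((κ−3)/2); SPACE minimizes
  ½ Σᵢ‖Xᵢ − Σ_{j≠i} ρ_ij √(s_jj/s_ii) X_j‖² + λ Σ|ρ_ij| by coordinate
  descent. WGCNA uses a_ij = |r_ij|^β with the topological overlap
  matrix TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(kᵢ,k_j) + 1 − a_ij).
* **Modularity.** Newman's Q = Σ_c [e_c/m − (d_c/2m)²], maximized by the
  partitioners and verified against exhaustive search on small graphs.
* **Enrichment.** One-sided hypergeometric tails per module × term,
  BH-corrected within module; ψ₁ = mean significant terms per enriched
  module, ψ₂ = total significant tests per annotated module.
* **Degree behavior.** Exact discrete power-law MLE
  (Hurwitz-zeta likelihood) with KS distance, plus log-log regression R².

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
default synthetic benchmark (10 regulon-sized modules of 3–8 genes, 100
conditions in duplicate, correlated regulator activities, a
compendium-wide condition effect, 5% noisy and 5% low-signal genes):

```sh
python analysis/01_simulate_compendium.py
python analysis/02_preprocess.py
python analysis/03_reconstruct_networks.py
python analysis/04_modules_and_enrichment.py
python analysis/05_benchmark_gold_standard.py
python analysis/06_screen_and_rank.py
```

Representative output (seed 1):

```
pearson   :   50 genes,   106 edges, n_e/n_g =  2.12, density 0.087, 24 hubs
space     :   82 genes,   165 edges, n_e/n_g =  2.01, density 0.050, 25 hubs
...
space     :  10 modules (Q = 0.718), 10 significant terms in 7 modules; psi1 = 1.43, psi2 = 1.43
genenet   :   3 modules (Q = 0.667), 0 significant terms in 0 modules; psi1 = 0.00, psi2 = 0.00
...
rank-sum over significant terms, psi1, psi2, Q, power-law R^2:
  1. space      (psi2 = 1.43, Q = 0.718)
  2. pearson    (psi2 = 1.00, Q = 0.865)
...
matched-edge-count modularity, 10 fresh seeds:
  mean Q(SPACE) = 0.713 vs mean Q(Pearson @ same n_e) = 0.587; SPACE more modular in 10/10 seeds
```

Reading this: at its own threshold each method recovers networks of
similar size, but SPACE's modules carry the most enriched gene sets
(highest ψ₂ and total significant terms), GeneNet's nearly-empty network
carries none, and when the Pearson network is forced to the same edge
count as SPACE's, its marginal-correlation edges blur module boundaries
and modularity drops — partial correlation prunes those indirect edges.
The gold-standard comparison (script 05) shows random edge addition
shifting the gold network's degree CDF rightward, toward the denser
co-expression network, exactly the behavior the screening criteria rely
on.

The same stages are available as a CLI (`gcnbench simulate | preprocess |
reconstruct | analyze | modules | enrich | benchmark | project | rank |
run`) and as library calls (`gcnbench.pipeline.compare_methods` runs one
full comparison).

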