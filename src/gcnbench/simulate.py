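"""Synthetic expression compendia with known co-expression structure.

The generator emulates a bacterial microarray compendium: a set of growth
conditions measured in replicate, with groups of genes (regulon-like
modules) driven by a shared latent regulator activity profile, a pool of
unstructured background genes, a small fraction of technically noisy
genes, and a fraction of genes whose signal sits below the detection
floor. Alongside the matrix it returns the full ground truth (module
memberships, true co-expression pairs, contaminated genes) so that every
downstream stage — filtering, reconstruction, module detection,
enrichment — can be scored against a known answer.

Model
-----
Each module ``m`` has a latent activity profile ``f_m(c) ~ N(0, 1)`` drawn
independently per condition. A member gene ``g`` with loading
``l_g ~ U(0.7, 1.0)`` is observed in sample ``s`` of condition ``c`` as

    x_gs = b_g + s_f * l_g * f_m(c) + eps_gs,   eps_gs ~ N(0, noise_sd^2)

where ``b_g ~ N(8, 1)`` is a gene-specific baseline on the log-signal
scale and the factor scale ``s_f`` is calibrated so that the expected
Pearson correlation between two member genes with average loadings equals
``within_module_cor``. Background genes are baseline plus noise only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import AnnotationTable
from .errors import ConfigurationError
from .network import DirectedRegNet, canonical_edge

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_expression",
    "simulate_annotations",
    "simulate_regulatory_network",
]

BASELINE_MEAN = 8.0  # log2-like microarray signal location
BASELINE_SD = 1.0
LOADING_RANGE = (0.7, 1.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic compendium.

    ``genes_per_module`` may be a single count or an inclusive ``(lo, hi)``
    range; with a range, module sizes are drawn uniformly, which mimics
    the broad regulon-size spectrum of bacterial regulatory networks.
    """

    n_modules: int = 8
    genes_per_module: int | tuple[int, int] = (4, 24)
    n_background: int = 40
    n_conditions: int = 100
    n_replicates: int = 2
    within_module_cor: float = 0.85
    noise_sd: float = 1.0
    frac_noisy_genes: float = 0.05
    frac_low_signal: float = 0.05
    seed: int = 0
    signed_loadings: bool = False
    global_effect_sd: float = 1.2
    factor_correlation: float = 0.3
    loading_range: tuple[float, float] = LOADING_RANGE

    def __post_init__(self) -> None:
        sizes = self.genes_per_module
        lo, hi = (sizes, sizes) if isinstance(sizes, int) else sizes
        if min(self.n_modules, lo, hi, self.n_conditions, self.n_replicates) < 1:
            raise ConfigurationError("module/gene/condition/replicate counts must be >= 1")
        if self.n_background < 0:
            raise ConfigurationError("n_background must be >= 0")
        if not 0.0 <= self.within_module_cor < 1.0:
            raise ConfigurationError("within_module_cor must lie in [0, 1)")
        for name in ("frac_noisy_genes", "frac_low_signal"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.global_effect_sd < 0:
            raise ConfigurationError("global_effect_sd must be >= 0")
        if not 0.0 <= self.factor_correlation < 1.0:
            raise ConfigurationError("factor_correlation must lie in [0, 1)")
        if not 0.0 < self.loading_range[0] <= self.loading_range[1]:
            raise ConfigurationError("loading_range must be an increasing positive pair")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic compendium.

    ``module_of`` labels every gene; background genes are singletons with
    label ``singleton:<gene>``. ``true_edges`` holds every within-module
    gene pair (the guilt-by-association target set). ``regulators`` names
    the latent driver of each module; these are latent activities, not
    rows of the matrix.
    """

    module_of: dict[str, str]
    true_edges: set[tuple[str, str]]
    regulators: list[str]
    true_annotations: dict[str, str] = field(default_factory=dict)
    noisy_genes: list[str] = field(default_factory=list)
    low_signal_genes: list[str] = field(default_factory=list)

    @property
    def modules(self) -> dict[str, list[str]]:
        """Planted (non-singleton) modules as module id → gene list."""
        out: dict[str, list[str]] = {}
        for gene, mod in self.module_of.items():
            if not mod.startswith("singleton:"):
                out.setdefault(mod, []).append(gene)
        for genes in out.values():
            genes.sort()
        return out


def _factor_scale(target_cor: float, noise_sd: float, global_sd: float,
                  loading_range: tuple[float, float]) -> float:
    """Scale of the module factor so that two member genes with mean
    loadings correlate at ``target_cor``.

    Mean-field calibration: with module signal variance A (at the mean
    loading) and shared global-effect covariance G = global_sd^2 / 4
    (mean susceptibility 1/2), r ≈ (A + G) / (A + G + sigma^2), solved
    for A."""
    if target_cor == 0.0:
        return 0.0
    l_mean = 0.5 * (loading_range[0] + loading_range[1])
    g_cov = global_sd**2 / 4.0
    a = target_cor * noise_sd**2 / (1.0 - target_cor) - g_cov
    if a <= 0:
        raise ConfigurationError(
            "global_effect_sd too large for the requested within_module_cor"
        )
    return math.sqrt(a) / l_mean


def simulate_expression(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a synthetic compendium.

    Returns
    -------
    matrix : DataFrame, genes × samples, log-scale signal
    design : DataFrame indexed by sample id with columns
        ``condition_id`` and ``replicate``
    truth : GroundTruth
    """
    rng = np.random.default_rng(config.seed)
    sizes_spec = config.genes_per_module
    if isinstance(sizes_spec, int):
        sizes = [sizes_spec] * config.n_modules
    else:
        lo, hi = sizes_spec
        sizes = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_modules)]

    n_module_genes = sum(sizes)
    n_genes = n_module_genes + config.n_background
    genes = [f"g{i:04d}" for i in range(n_genes)]
    n_samples = config.n_conditions * config.n_replicates
    sample_ids = [
        f"c{c:03d}_r{r + 1}"
        for c in range(config.n_conditions)
        for r in range(config.n_replicates)
    ]
    cond_of_sample = np.repeat(np.arange(config.n_conditions), config.n_replicates)

    module_of: dict[str, str] = {}
    true_edges: set[tuple[str, str]] = set()
    regulators = [f"reg_M{m}" for m in range(config.n_modules)]

    # latent regulator activities, one unit-variance profile per module;
    # a shared super-factor correlates them pairwise at factor_correlation,
    # mimicking the growth-rate coupling of bacterial regulon activities
    c_f = config.factor_correlation
    super_factor = rng.standard_normal(config.n_conditions)
    factors = (
        math.sqrt(c_f) * super_factor[None, :]
        + math.sqrt(1.0 - c_f) * rng.standard_normal((config.n_modules, config.n_conditions))
    )
    s_f = _factor_scale(config.within_module_cor, config.noise_sd,
                        config.global_effect_sd, config.loading_range)

    # compendium-wide condition effect (growth phase / batch trend) hitting
    # every gene with its own susceptibility; marginal correlations inherit
    # it, direct (partial) associations do not
    global_profile = rng.standard_normal(config.n_conditions)
    susceptibility = rng.uniform(0.0, 1.0, size=n_genes)

    baselines = BASELINE_MEAN + BASELINE_SD * rng.standard_normal(n_genes)
    values = np.empty((n_genes, n_samples))
    row = 0
    for m, size in enumerate(sizes):
        members = genes[row : row + size]
        loadings = rng.uniform(*config.loading_range, size=size)
        if config.signed_loadings:
            loadings *= rng.choice([-1.0, 1.0], size=size)
        signal = s_f * loadings[:, None] * factors[m][cond_of_sample][None, :]
        values[row : row + size] = baselines[row : row + size, None] + signal
        for g in members:
            module_of[g] = f"M{m}"
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                true_edges.add(canonical_edge(a, b))
        row += size
    for g in genes[row:]:
        module_of[g] = f"singleton:{g}"
    values[row:] = baselines[row:, None]

    values += (
        config.global_effect_sd
        * susceptibility[:, None]
        * global_profile[cond_of_sample][None, :]
    )

    noise = config.noise_sd * rng.standard_normal((n_genes, n_samples))

    # technically noisy genes: replicate variance inflated tenfold
    n_noisy = int(round(config.frac_noisy_genes * n_genes))
    noisy_idx = rng.choice(n_genes, size=n_noisy, replace=False) if n_noisy else np.array([], dtype=int)
    noise[noisy_idx] *= math.sqrt(10.0)
    values += noise

    # low-signal genes: shifted below the detection floor (5th percentile
    # of the global signal distribution)
    remaining = np.setdiff1d(np.arange(n_genes), noisy_idx)
    n_low = min(int(round(config.frac_low_signal * n_genes)), remaining.size)
    low_idx = rng.choice(remaining, size=n_low, replace=False) if n_low else np.array([], dtype=int)
    if n_low:
        floor = np.quantile(values, 0.05)
        for i in low_idx:
            # park the gene's median 3 noise-sd below the floor so the bulk
            # of its signal sits under the detection limit
            shift = np.median(values[i]) - floor + 3.0 * config.noise_sd
            values[i] -= shift

    matrix = pd.DataFrame(values, index=genes, columns=sample_ids)
    design = pd.DataFrame(
        {
            "condition_id": [f"c{c:03d}" for c in cond_of_sample],
            "replicate": np.tile(np.arange(1, config.n_replicates + 1), config.n_conditions),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = GroundTruth(
        module_of=module_of,
        true_edges=true_edges,
        regulators=regulators,
        noisy_genes=sorted(genes[i] for i in noisy_idx),
        low_signal_genes=sorted(genes[i] for i in low_idx),
    )
    return matrix, design, truth


def simulate_annotations(
    truth: GroundTruth,
    n_terms: int,
    frac_correct: float = 0.9,
    seed: int = 0,
    background_rate: float = 0.02,
) -> AnnotationTable:
    """GO-style flat annotations concentrated in the planted modules.

    Each planted module gets one dedicated term covering ``frac_correct``
    of its genes; every other (term, gene) assignment is uniform random at
    ``background_rate``. Records the dedicated term of each module in
    ``truth.true_annotations``.
    """
    if not 0.0 <= frac_correct <= 1.0:
        raise ConfigurationError("frac_correct must lie in [0, 1]")
    modules = truth.modules
    if n_terms < len(modules):
        raise ConfigurationError(
            f"n_terms={n_terms} is smaller than the number of planted modules ({len(modules)})"
        )
    rng = np.random.default_rng(seed)
    universe = sorted(truth.module_of)
    terms = [f"T{t:03d}" for t in range(n_terms)]
    gene_terms: dict[str, set[str]] = {g: set() for g in universe}

    truth.true_annotations = {}
    for term, mod in zip(terms, sorted(modules)):
        members = modules[mod]
        n_hit = math.ceil(frac_correct * len(members))
        hits = rng.choice(members, size=n_hit, replace=False) if n_hit else []
        for g in hits:
            gene_terms[g].add(term)
        truth.true_annotations[mod] = term

    # uniform random background assignments for every term
    mask = rng.random((n_terms, len(universe))) < background_rate
    for t, term in enumerate(terms):
        for g_idx in np.nonzero(mask[t])[0]:
            gene_terms[universe[g_idx]].add(term)
    return AnnotationTable.from_gene_terms(gene_terms, universe=universe, all_terms=terms)


def simulate_regulatory_network(
    n_genes: int,
    n_hub_regulators: int,
    attachment_exponent: float = 1.0,
    seed: int = 0,
    hub_out_degree: int = 120,
) -> DirectedRegNet:
    """Scale-free directed TF→target gold standard.

    The network grows by degree-proportional attachment: each new gene
    receives one incoming regulatory edge from an existing gene chosen
    with probability ∝ (out_degree + 1)^attachment_exponent, producing a
    long-tailed out-degree distribution. The first ``n_hub_regulators``
    genes are then forced to ``hub_out_degree`` targets, emulating
    sigma-factor-like global regulators that control over a hundred genes.
    """
    if not n_genes > n_hub_regulators >= 0:
        raise ConfigurationError("need n_genes > n_hub_regulators >= 0")
    if attachment_exponent <= 0:
        raise ConfigurationError("attachment_exponent must be positive")
    rng = np.random.default_rng(seed)
    names = [f"g{i:04d}" for i in range(n_genes)]
    edges: list[tuple[str, str]] = [(names[0], names[1])]
    edge_set = {(0, 1)}
    out_deg = np.zeros(n_genes)
    out_deg[0] = 1.0
    for i in range(2, n_genes):
        weights = (out_deg[:i] + 1.0) ** attachment_exponent
        u = rng.choice(i, p=weights / weights.sum())
        edges.append((names[u], names[i]))
        edge_set.add((int(u), i))
        out_deg[u] += 1
    for h in range(n_hub_regulators):
        candidates = np.array(
            [t for t in range(n_genes) if t != h and (h, t) not in edge_set]
        )
        need = hub_out_degree - int(out_deg[h])
        if need > 0:
            targets = rng.choice(candidates, size=min(need, candidates.size), replace=False)
            for t in targets:
                edges.append((names[h], names[int(t)]))
                edge_set.add((h, int(t)))
                out_deg[h] += 1
    return DirectedRegNet(edges=edges)
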