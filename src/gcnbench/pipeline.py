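"""End-to-end orchestration: simulate → preprocess → reconstruct →
modules → topology → enrich → screen → rank.

Two entry points:

* :func:`compare_methods` — the method-comparison study on one synthetic
  compendium: builds a network per reconstruction method at its
  benchmark threshold, partitions it with Walk-trap, scores structure,
  power-law behavior and module enrichment (ψ statistics), and adds the
  matched-edge-count modularity comparison between the Pearson and SPACE
  networks.
* :func:`run_pipeline` — the same flow driven by a :class:`PipelineConfig`,
  writing every intermediate artifact to an output directory.

The benchmark compendium (:data:`BENCHMARK_SIM`) emulates a bacterial
microarray compendium at desk scale: ten regulon-sized modules of 3–8
genes, strongly correlated regulator activities, a compendium-wide
condition effect, background genes and contaminated genes. Reconstruction
thresholds for the partial-correlation methods are scaled to this regime
(planted partial correlations are an order of magnitude smaller than the
marginal correlations).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import yaml

from . import io as gio
from .benchmark import MethodReport, rank_methods
from .community import detect_modules
from .enrichment import psi_summary, enrich_modules
from .errors import ConfigurationError
from .network import Network
from .preprocess import aggregate_replicates, filter_genes
from .reconstruct import (
    correlation_matrix,
    correlation_network,
    genenet_network,
    network_from_scores,
    space_network,
    space_pcor,
    wgcna_network,
)
from .simulate import SimulationConfig, simulate_annotations, simulate_expression
from .topology import degree_distribution, fit_power_law, summarize_structure

__all__ = [
    "BENCHMARK_SIM",
    "BENCHMARK_METHOD_PARAMS",
    "PipelineConfig",
    "stage_seed",
    "reconstruct_by_method",
    "compare_methods",
    "run_pipeline",
]

# Study conditions of the default synthetic benchmark (see docs/methods.md).
BENCHMARK_SIM = SimulationConfig(
    n_modules=10,
    genes_per_module=(3, 8),
    n_background=30,
    n_conditions=100,
    n_replicates=2,
    within_module_cor=0.85,
    noise_sd=1.0,
    frac_noisy_genes=0.05,
    frac_low_signal=0.05,
    global_effect_sd=0.8,
    factor_correlation=0.75,
    loading_range=(0.5, 1.0),
)

# Per-method benchmark thresholds. Correlation-based methods use the
# stringent |r| = 0.8 regime; the partial-correlation methods use
# thresholds on their own (much smaller) association scale.
BENCHMARK_METHOD_PARAMS: dict[str, dict[str, Any]] = {
    "pearson": {"r_threshold": 0.8},
    "spearman": {"r_threshold": 0.8},
    "genenet": {"omega": 0.9},
    "space": {"rho_threshold": 0.06, "lambda_scale": 1.0},
    "wgcna": {"beta": 5, "tau": 0.8**5},
}

METHODS = tuple(BENCHMARK_METHOD_PARAMS)


def stage_seed(global_seed: int, stage: str) -> int:
    """Fan the global seed out to a stable per-stage seed."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def reconstruct_by_method(matrix, method: str, **params) -> Network:
    """Dispatch to one of the five reconstruction methods."""
    if method in ("pearson", "spearman"):
        return correlation_network(matrix, method=method, **params)
    if method == "genenet":
        return genenet_network(matrix, **params)
    if method == "space":
        return space_network(matrix, **params)
    if method == "wgcna":
        net, _ = wgcna_network(matrix, **params)
        return net
    raise ConfigurationError(f"unknown reconstruction method {method!r}; choose from {METHODS}")


def _method_report(method: str, net: Network, annotations, alpha: float,
                   min_module_size: int, lp_seed: int) -> MethodReport | None:
    if net.n_e < 3 or net.n_g < 4:
        return None
    partition = detect_modules(net, "walktrap", min_module_size=min_module_size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = enrich_modules(partition, annotations, alpha=alpha,
                                 min_module_size=min_module_size)
        summary = psi_summary(results, partition, alpha=alpha)
        try:
            plaw = fit_power_law(degree_distribution(net), "loglog_regression")
        except ValueError:
            plaw = None
    if plaw is None:
        return None
    return MethodReport(
        method=method,
        structure=summarize_structure(net),
        powerlaw=plaw,
        enrichment=summary,
        q=partition.q,
    )


def compare_methods(
    seed: int,
    sim_config: SimulationConfig | None = None,
    method_params: dict[str, dict[str, Any]] | None = None,
    alpha: float = 0.05,
    min_module_size: int = 5,
    n_terms: int | None = None,
) -> dict[str, Any]:
    """Run the five-method comparison on one synthetic compendium.

    Returns a dict with per-method :class:`MethodReport`s (methods whose
    network collapsed below a usable size are reported as ``None``), the
    ground truth, and the matched-edge-count Pearson-vs-SPACE modularity
    comparison (``q_space`` vs ``q_pearson_matched``).
    """
    base = sim_config or BENCHMARK_SIM
    params = method_params or BENCHMARK_METHOD_PARAMS
    cfg = dataclasses.replace(base, seed=stage_seed(seed, "simulate"))
    matrix, design, truth = simulate_expression(cfg)
    annotations = simulate_annotations(
        truth,
        n_terms=n_terms if n_terms is not None else 2 * cfg.n_modules + 4,
        frac_correct=0.9,
        seed=stage_seed(seed, "annotations"),
    )
    filtered, removed = filter_genes(matrix, design)
    expr = aggregate_replicates(filtered, design)

    reports: dict[str, MethodReport | None] = {}
    networks: dict[str, Network] = {}
    for method in params:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = reconstruct_by_method(expr, method, **params[method])
        networks[method] = net
        reports[method] = _method_report(method, net, annotations, alpha,
                                         min_module_size, stage_seed(seed, "lp"))

    # matched-edge-count comparison: Pearson network with the same number
    # of edges as the SPACE network, versus the SPACE network itself
    matched: dict[str, float] = {}
    space_net = networks.get("space")
    if space_net is not None and space_net.n_e >= 3:
        genes, r = correlation_matrix(expr, "pearson")
        iu = np.triu_indices(len(genes), k=1)
        absr = np.abs(r[iu])
        if space_net.n_e <= absr.size:
            thr = float(np.sort(absr)[-space_net.n_e])
            pe_net = network_from_scores(genes, r, thr)
            pe_part = detect_modules(pe_net, "walktrap", min_module_size=min_module_size)
            sp_part = detect_modules(space_net, "walktrap", min_module_size=min_module_size)
            matched = {
                "q_space": sp_part.q,
                "q_pearson_matched": pe_part.q,
                "n_e": space_net.n_e,
                "pearson_threshold": thr,
            }
    return {
        "config": cfg,
        "truth": truth,
        "annotations": annotations,
        "expression": expr,
        "removed_genes": removed,
        "networks": networks,
        "reports": reports,
        "matched_modularity": matched,
    }


# --------------------------------------------------------------------------
# Config-driven pipeline


_STAGES = ("simulate", "preprocess", "reconstruct", "modules", "enrichment", "screening")


@dataclass
class PipelineConfig:
    """Full-pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    outdir: str = "results/pipeline"
    log_level: str = "INFO"
    simulate: dict[str, Any] = field(default_factory=dict)
    preprocess: dict[str, Any] = field(default_factory=dict)
    reconstruct: dict[str, Any] = field(default_factory=dict)
    modules: dict[str, Any] = field(default_factory=dict)
    enrichment: dict[str, Any] = field(default_factory=dict)
    screening: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def effective(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        sim = dataclasses.asdict(dataclasses.replace(BENCHMARK_SIM, **self.simulate))
        out["simulate"] = sim
        out["reconstruct"] = {
            m: {**BENCHMARK_METHOD_PARAMS[m], **self.reconstruct.get(m, {})}
            for m in self.reconstruct.get("methods", METHODS)
            if m != "methods"
        }
        return out

    def config_hash(self) -> str:
        eff = self.effective()
        eff.pop("outdir", None)  # hash covers scientific parameters only
        eff.pop("log_level", None)
        blob = yaml.safe_dump(eff, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full pipeline and persist every intermediate artifact.

    Deterministic under ``config.seed``: two runs with the same config
    produce byte-identical outputs.
    """
    eff = config.effective()
    os.makedirs(config.outdir, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed}

    sim_cfg = dataclasses.replace(
        BENCHMARK_SIM, **{**config.simulate, "seed": stage_seed(config.seed, "simulate")}
    )
    result = compare_methods(
        config.seed,
        sim_config=sim_cfg,
        method_params=eff["reconstruct"],
        alpha=config.enrichment.get("alpha", 0.05),
        min_module_size=config.modules.get("min_module_size", 5),
    )

    gio.write_expression(result["expression"], os.path.join(config.outdir, "expression.tsv"), meta)
    gio.write_annotations(result["annotations"], os.path.join(config.outdir, "annotations.tsv"), meta)
    gio.write_truth(result["truth"], config.outdir, meta)

    summary_rows = []
    for method, net in result["networks"].items():
        if net.n_e:
            gio.write_network(net, os.path.join(config.outdir, f"net_{method}.tsv"), meta=meta)
        rep = result["reports"][method]
        if rep is None:
            summary_rows.append({"method": method, "usable": False})
            continue
        s = rep.structure
        summary_rows.append({
            "method": method, "usable": True,
            "n_g": s.n_g, "n_e": s.n_e,
            "density": round(s.density, 6),
            "edge_gene_ratio": round(s.edge_gene_ratio, 4),
            "q": round(rep.q, 4),
            "powerlaw_r2": round(rep.powerlaw.r2_loglog, 4),
            "psi1": round(rep.enrichment.psi1, 4),
            "psi2": round(rep.enrichment.psi2, 4),
            "significant_terms": rep.enrichment.total_significant_terms,
        })
    usable = [r for m, r in result["reports"].items() if r is not None]
    ranking = [
        {"method": r.method, "overall_rank": r.overall_rank, **{k: v for k, v in r.ranks.items()}}
        for r in rank_methods(usable)
    ] if len(usable) >= 2 else []

    bundle = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "methods": summary_rows,
        "ranking": ranking,
        "matched_modularity": result["matched_modularity"],
        "n_removed_genes": len(result["removed_genes"]),
    }
    with open(os.path.join(config.outdir, "summary.json"), "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
    with open(os.path.join(config.outdir, "effective_config.yaml"), "w") as fh:
        yaml.safe_dump(eff, fh, sort_keys=True)
    return bundle
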