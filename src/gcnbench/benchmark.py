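"""Gold-standard comparison, candidate screening, method ranking and
recovery metrics.

Regulatory gold standards (RegulonDB / SubtiWiki exports, or simulated
equivalents) are directed TF→target networks; for structural comparison
they are collapsed to undirected co-expression-style graphs. Candidate
co-expression networks are screened on modularity, size and the
edges-to-genes ratio n_e/n_g against the gold standards' ratios, and the
reconstruction methods are ranked on enrichment and structural criteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score

from .community import Partition
from .enrichment import EnrichmentSummary
from .errors import ConfigurationError
from .network import DirectedRegNet, Network, canonical_edge
from .simulate import GroundTruth
from .topology import DegreeDistribution, PowerLawFit, StructuralSummary

__all__ = [
    "ScreeningCriteria",
    "MethodReport",
    "EdgeRecovery",
    "undirect_network",
    "add_random_edges",
    "ks_degree_distance",
    "screen_candidates",
    "rank_methods",
    "edge_recovery",
    "partition_similarity",
    "project_gene_sets",
]


@dataclass
class ScreeningCriteria:
    """Operational form of the discard rules for candidate networks."""

    q_min: float = 0.5
    g_min: int = 500
    ratio_max: float = 10.0
    gold_ratios: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.q_min <= 0 or self.g_min <= 0 or self.ratio_max <= 0:
            raise ConfigurationError("screening criteria must all be positive")


@dataclass
class MethodReport:
    """Per-method bundle of structural and enrichment summaries."""

    method: str
    structure: StructuralSummary | None = None
    powerlaw: PowerLawFit | None = None
    enrichment: EnrichmentSummary | None = None
    q: float = float("nan")
    ranks: dict[str, float] = field(default_factory=dict)
    overall_rank: int | None = None


@dataclass
class EdgeRecovery:
    precision: float
    recall: float
    f1: float
    empty_prediction: bool = False


def undirect_network(regnet: DirectedRegNet) -> Network:
    """Drop edge directions; reciprocal pairs collapse to one edge."""
    net = Network()
    for reg, tgt in regnet.edges:
        key = canonical_edge(reg, tgt)
        if key not in net.edges:
            net.edges[key] = 1.0
    return net


def add_random_edges(network: Network, phi: float, seed: int = 0) -> Network:
    """Probabilistic random edge addition for structural robustness tests.

    Adds exactly ceil(phi * n_e) new edges between currently non-adjacent
    gene pairs, sampling endpoints with probability proportional to their
    degree (so the product-of-degrees weight favors hub attachment and
    shifts the degree distribution rightward without erasing the tail).
    Original edges are untouched.
    """
    if phi < 0:
        raise ConfigurationError("phi must be >= 0")
    n_add = math.ceil(phi * network.n_e)
    out = Network(edges=dict(network.edges))
    if n_add == 0:
        return out
    genes = network.genes
    n = len(genes)
    capacity = n * (n - 1) // 2 - network.n_e
    if capacity < n_add:
        raise ValueError(f"cannot add {n_add} edges: only {capacity} non-adjacent pairs exist")
    deg = network.degree()
    weights = np.array([deg[g] for g in genes], dtype=float)
    probs = weights / weights.sum()
    rng = np.random.default_rng(seed)
    added = 0
    while added < n_add:
        a, b = rng.choice(n, size=2, p=probs)
        if a == b:
            continue
        key = canonical_edge(genes[a], genes[b])
        if key in out.edges:
            continue
        out.edges[key] = 1.0
        added += 1
    return out


def ks_degree_distance(a: DegreeDistribution, b: DegreeDistribution) -> float:
    """Kolmogorov–Smirnov distance between two empirical degree CDFs."""
    if not a.pk or not b.pk:
        raise ValueError("degree distributions must be non-empty")
    support = sorted(set(a.pk) | set(b.pk))
    fa = np.cumsum([a.pk.get(k, 0.0) for k in support])
    fb = np.cumsum([b.pk.get(k, 0.0) for k in support])
    return float(np.abs(fa - fb).max())


def screen_candidates(
    candidates: list[tuple[Network, Partition]],
    criteria: ScreeningCriteria,
) -> tuple[list[tuple[Network, Partition]], list[tuple[Network, Partition, str]]]:
    """Apply the discard rules; order survivors by gold-ratio proximity.

    Discards candidates with low modularity (Q < q_min), very sparse
    connectivity (n_g < g_min) or very high connectivity
    (n_e/n_g > ratio_max). Survivors are ordered by the absolute
    difference between their n_e/n_g and the nearest gold-standard ratio
    (input order when no gold ratios are given).
    """
    if not candidates:
        raise ConfigurationError("no candidate networks to screen")
    kept: list[tuple[Network, Partition]] = []
    discarded: list[tuple[Network, Partition, str]] = []
    for net, part in candidates:
        if net.n_g < criteria.g_min:
            discarded.append((net, part, "very sparse connectivity"))
        elif net.n_e / net.n_g > criteria.ratio_max:
            discarded.append((net, part, "very high connectivity"))
        elif part.q < criteria.q_min:
            discarded.append((net, part, "low modularity"))
        else:
            kept.append((net, part))
    if criteria.gold_ratios:
        def distance(item: tuple[Network, Partition]) -> float:
            ratio = item[0].n_e / item[0].n_g
            return min(abs(ratio - g) for g in criteria.gold_ratios)
        kept.sort(key=distance)
    return kept, discarded


_RANK_CRITERIA = {
    "total_significant_terms": lambda r: r.enrichment.total_significant_terms,
    "psi1": lambda r: r.enrichment.psi1,
    "psi2": lambda r: r.enrichment.psi2,
    "q": lambda r: r.q,
    "powerlaw_r2": lambda r: r.powerlaw.r2_loglog,
}


def rank_methods(reports: list[MethodReport]) -> list[MethodReport]:
    """Rank methods by rank-sum over enrichment and structural criteria.

    Criteria (higher is better): total significant terms, psi1, psi2,
    best-partition Q, and the log-log R^2 of the power-law fit. Ties in
    the rank-sum are broken by psi2. Returns the reports sorted best
    first, with per-criterion ranks filled in.
    """
    if len(reports) < 2:
        raise ConfigurationError("need at least 2 method reports to rank")
    for rep in reports:
        for fname in ("enrichment", "powerlaw"):
            if getattr(rep, fname) is None:
                raise ConfigurationError(f"report for {rep.method!r} is missing {fname}")
        if math.isnan(rep.q):
            raise ConfigurationError(f"report for {rep.method!r} is missing q")
    for name, getter in _RANK_CRITERIA.items():
        values = np.array([getter(r) for r in reports], dtype=float)
        values = np.where(np.isnan(values), -np.inf, values)
        ranks = rankdata(-values, method="average")
        for rep, rk in zip(reports, ranks):
            rep.ranks[name] = float(rk)
    order = sorted(
        reports,
        key=lambda r: (sum(r.ranks.values()), -r.enrichment.psi2, r.method),
    )
    for pos, rep in enumerate(order, start=1):
        rep.overall_rank = pos
    return order


def edge_recovery(predicted: Network, truth: GroundTruth) -> EdgeRecovery:
    """Precision/recall/F1 of the predicted edge set against the planted
    within-module pairs, restricted to genes present in both."""
    shared = set(predicted.genes) & set(truth.module_of)
    pred = {e for e in predicted.edges if e[0] in shared and e[1] in shared}
    true = {e for e in truth.true_edges if e[0] in shared and e[1] in shared}
    if not pred:
        return EdgeRecovery(0.0, 0.0, 0.0, empty_prediction=True)
    tp = len(pred & true)
    precision = tp / len(pred)
    recall = tp / len(true) if true else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return EdgeRecovery(precision, recall, f1)


def partition_similarity(a: Partition | dict[str, object], b: Partition | dict[str, object]) -> float:
    """Adjusted Rand index between two partitions on their shared genes."""
    map_a = a.module_of if isinstance(a, Partition) else dict(a)
    map_b = b.module_of if isinstance(b, Partition) else dict(b)
    shared = sorted(set(map_a) & set(map_b))
    if not shared:
        raise ValueError("partitions share no genes")
    la = [map_a[g] for g in shared]
    lb = [map_b[g] for g in shared]
    return float(adjusted_rand_score(la, lb))


def project_gene_sets(
    partition: Partition,
    network: Network,
    gene_sets: dict[str, set[str] | list[str]],
) -> list[dict]:
    """Project named gene sets (regulons, operons) onto network modules.

    For each set: coverage = fraction of its genes present in the network;
    cohesion = largest fraction of the covered genes falling into a single
    module; plus the per-module membership breakdown. Sets absent from the
    network get coverage 0 and undefined (NaN) cohesion.
    """
    if not gene_sets:
        raise ConfigurationError("gene_sets must be non-empty")
    net_genes = set(network.genes)
    rows: list[dict] = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name])
        if not members:
            raise ConfigurationError(f"gene set {name!r} is empty")
        covered = members & net_genes
        coverage = len(covered) / len(members)
        breakdown: dict[int, int] = {}
        for g in covered:
            mod = partition.module_of.get(g)
            if mod is not None:
                breakdown[mod] = breakdown.get(mod, 0) + 1
        cohesion = max(breakdown.values()) / len(covered) if covered and breakdown else float("nan")
        rows.append({
            "set": name,
            "size": len(members),
            "coverage": coverage,
            "cohesion": cohesion,
            "modules": dict(sorted(breakdown.items())),
        })
    return rows
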