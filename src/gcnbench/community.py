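"""Module detection: graph partitioners and Newman modularity.

The partitioners mirror the comparison set used for bacterial GCN module
detection: Walk-trap (random-walk distances, agglomerative), Fast-Greedy
(greedy modularity maximization) and asynchronous label propagation.
The heavy lifting is delegated to igraph; modularity Q is computed by our
own implementation of the Newman formula so partitions from any source
(including external partition files) are scored identically.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

import igraph as ig

from .errors import ConfigurationError
from .network import Network

__all__ = [
    "Partition",
    "modularity",
    "walktrap_partition",
    "fastgreedy_partition",
    "label_propagation_partition",
    "detect_modules",
    "PARTITIONERS",
]


@dataclass
class Partition:
    """Disjoint assignment of network genes to modules.

    ``modules`` is ordered by decreasing size, so "module 0" is always the
    largest module. ``q`` is the (unweighted) Newman modularity of the
    partition on the network it was computed from.
    """

    module_of: dict[str, int]
    modules: list[list[str]]
    q: float
    method: str
    params: dict = field(default_factory=dict)

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def sizes(self) -> list[int]:
        return [len(m) for m in self.modules]

    @classmethod
    def from_labels(
        cls,
        genes: Sequence[str],
        labels: Sequence[int],
        network: Network | None = None,
        method: str = "external",
        params: dict | None = None,
    ) -> "Partition":
        """Build a size-ordered partition from raw cluster labels."""
        groups: dict[int, list[str]] = {}
        for g, lab in zip(genes, labels):
            groups.setdefault(lab, []).append(g)
        # decreasing size; ties broken by smallest member for determinism
        ordered = sorted(groups.values(), key=lambda ms: (-len(ms), min(ms)))
        modules = [sorted(ms) for ms in ordered]
        module_of = {g: i for i, ms in enumerate(modules) for g in ms}
        q = modularity(network, module_of) if network is not None else float("nan")
        return cls(module_of=module_of, modules=modules, q=q,
                   method=method, params=params or {})


def modularity(network: Network, partition: Partition | dict[str, int]) -> float:
    """Newman modularity Q = sum_c [e_c/m - (d_c/(2m))^2], unweighted.

    ``e_c`` counts intra-module edges, ``d_c`` is the total degree of
    module ``c`` and ``m`` the number of edges in the network.
    """
    if network.n_e == 0:
        raise ValueError("modularity is undefined on an empty network")
    module_of = partition.module_of if isinstance(partition, Partition) else partition
    missing = [g for g in network.genes if g not in module_of]
    if missing:
        raise ValueError(f"partition does not cover gene(s) {missing[:3]}")
    m = network.n_e
    intra: dict[int | str, int] = {}
    deg_tot: dict[int | str, int] = {}
    for a, b, _ in network:
        ca, cb = module_of[a], module_of[b]
        deg_tot[ca] = deg_tot.get(ca, 0) + 1
        deg_tot[cb] = deg_tot.get(cb, 0) + 1
        if ca == cb:
            intra[ca] = intra.get(ca, 0) + 1
    q = 0.0
    for c, d_c in deg_tot.items():
        q += intra.get(c, 0) / m - (d_c / (2.0 * m)) ** 2
    return q


def _to_igraph(network: Network) -> tuple[ig.Graph, list[str]]:
    genes = network.genes
    index = {g: i for i, g in enumerate(genes)}
    edges = [(index[a], index[b]) for a, b, _ in network]
    g = ig.Graph(n=len(genes), edges=edges, directed=False)
    return g, genes


def _finalize(network: Network, genes: list[str], labels: Sequence[int],
              method: str, params: dict) -> Partition:
    return Partition.from_labels(genes, labels, network=network,
                                 method=method, params=params)


def walktrap_partition(network: Network, t: int = 4) -> Partition:
    """Walk-trap: agglomerative clustering on t-step random-walk distances;
    the cut with maximal Q along the merge sequence is returned."""
    if t < 1:
        raise ConfigurationError("walk length t must be >= 1")
    g, genes = _to_igraph(network)
    dendro = g.community_walktrap(steps=t)
    clustering = dendro.as_clustering()  # max-modularity cut
    return _finalize(network, genes, clustering.membership, "walktrap", {"t": t})


def fastgreedy_partition(network: Network) -> Partition:
    """Fast-Greedy agglomerative modularity maximization."""
    g, genes = _to_igraph(network)
    dendro = g.community_fastgreedy()
    clustering = dendro.as_clustering()
    return _finalize(network, genes, clustering.membership, "fastgreedy", {})


def label_propagation_partition(network: Network, seed: int = 0) -> Partition:
    """Asynchronous label propagation with seeded random update order."""
    g, genes = _to_igraph(network)
    state = random.Random(seed)
    ig.set_random_number_generator(state)
    try:
        clustering = g.community_label_propagation()
    finally:
        ig.set_random_number_generator(random)
    return _finalize(network, genes, clustering.membership, "label_propagation",
                     {"seed": seed})


PARTITIONERS = {
    "walktrap": walktrap_partition,
    "fastgreedy": fastgreedy_partition,
    "label_propagation": label_propagation_partition,
}


def detect_modules(
    network: Network,
    method: str = "walktrap",
    min_module_size: int = 5,
    **params,
) -> Partition:
    """Dispatch to a partitioner and flag modules eligible for enrichment.

    Modules with fewer than ``min_module_size`` genes are retained in the
    partition but listed in ``partition.params['ineligible_modules']`` so
    that enrichment can skip them.
    """
    if method not in PARTITIONERS:
        raise ConfigurationError(
            f"unknown partitioner {method!r}; available: {sorted(PARTITIONERS)}; "
            "externally computed partitions can be loaded with io.read_partition"
        )
    partition = PARTITIONERS[method](network, **params)
    partition.params["min_module_size"] = min_module_size
    partition.params["ineligible_modules"] = [
        i for i, ms in enumerate(partition.modules) if len(ms) < min_module_size
    ]
    return partition
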