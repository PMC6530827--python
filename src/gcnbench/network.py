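"""Undirected weighted gene networks.

The :class:`Network` is the central object of the pipeline: a simple
undirected graph over genes with a real association score on every edge.
Genes that fail the inclusion threshold of a reconstruction method (i.e.
end up isolated) are excluded from the node list, so ``n_g`` counts only
connected genes and the edges-to-genes ratio ``n_e / n_g`` is directly
comparable across methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx

__all__ = ["Network", "DirectedRegNet", "canonical_edge"]


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Order an unordered gene pair lexicographically."""
    return (a, b) if a <= b else (b, a)


@dataclass
class Network:
    """Simple undirected weighted graph over genes.

    Attributes
    ----------
    edges
        Mapping from lexicographically ordered gene pairs to association
        weights. No self-loops, no duplicates by construction.
    """

    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    @classmethod
    def from_edges(cls, triples: Iterable[tuple[str, str, float]]) -> "Network":
        net = cls()
        for a, b, w in triples:
            net.add_edge(a, b, w)
        return net

    def add_edge(self, a: str, b: str, weight: float = 1.0) -> None:
        if a == b:
            raise ValueError(f"self-loop on gene {a!r} is not allowed")
        key = canonical_edge(a, b)
        if key in self.edges:
            raise ValueError(f"duplicate edge {key}")
        self.edges[key] = float(weight)

    @property
    def genes(self) -> list[str]:
        """Sorted list of genes incident to at least one edge."""
        seen: set[str] = set()
        for a, b in self.edges:
            seen.add(a)
            seen.add(b)
        return sorted(seen)

    @property
    def n_g(self) -> int:
        return len(self.genes)

    @property
    def n_e(self) -> int:
        return len(self.edges)

    def has_edge(self, a: str, b: str) -> bool:
        return canonical_edge(a, b) in self.edges

    def degree(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for a, b in self.edges:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        return deg

    def neighbors(self, gene: str) -> set[str]:
        out = set()
        for a, b in self.edges:
            if a == gene:
                out.add(b)
            elif b == gene:
                out.add(a)
        return out

    def __iter__(self) -> Iterator[tuple[str, str, float]]:
        for (a, b), w in sorted(self.edges.items()):
            yield a, b, w

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.genes)
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        if g.is_directed():
            raise ValueError("directed graph; collapse it with undirect_network first")
        net = cls()
        for a, b, data in g.edges(data=True):
            net.add_edge(str(a), str(b), float(data.get("weight", 1.0)))
        return net


@dataclass
class DirectedRegNet:
    """Directed regulator → target network (gold-standard shape).

    Mirrors the RegulonDB / SubtiWiki export format: a list of directed
    TF→target interactions, optionally signed. Self-edges are forbidden
    and duplicates are collapsed on construction.
    """

    edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        clean: list[tuple[str, str]] = []
        for reg, tgt in self.edges:
            if reg == tgt:
                raise ValueError(f"self-edge on {reg!r} is not allowed")
            if (reg, tgt) not in seen:
                seen.add((reg, tgt))
                clean.append((reg, tgt))
        self.edges = clean

    @property
    def nodes(self) -> list[str]:
        seen: set[str] = set()
        for a, b in self.edges:
            seen.add(a)
            seen.add(b)
        return sorted(seen)

    def out_degree(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for reg, _ in self.edges:
            deg[reg] = deg.get(reg, 0) + 1
        return deg
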