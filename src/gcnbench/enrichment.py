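"""Per-module gene-set overrepresentation (Fisher's exact test) and the
ψ1/ψ2 network-quality statistics.

Each network module is tested for overrepresentation of every annotation
term it touches with a one-sided hypergeometric (Fisher's exact) test,
corrected for multiple testing within the module. Two summary statistics
condense the result for network screening:

* ψ1 — average number of significant terms per enriched module (a module
  is *enriched* when it carries at least one significant term);
* ψ2 — total number of significant tests divided by the number of
  modules carrying at least one *annotated* term, whether significant or
  not. The alternative, stricter denominator (enriched modules only) is
  also reported as ``psi2_literal``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .community import Partition
from .errors import ConfigurationError

__all__ = [
    "AnnotationTable",
    "EnrichmentResult",
    "EnrichmentSummary",
    "fisher_overrepresentation",
    "enrich_modules",
    "psi_summary",
]


@dataclass
class AnnotationTable:
    """Flat gene → term annotations with an inverted term → genes index."""

    gene_terms: dict[str, set[str]]
    term_genes: dict[str, set[str]]
    universe: list[str]

    @classmethod
    def from_gene_terms(
        cls,
        gene_terms: Mapping[str, Iterable[str]],
        universe: Iterable[str] | None = None,
        all_terms: Iterable[str] | None = None,
    ) -> "AnnotationTable":
        fwd = {g: set(ts) for g, ts in gene_terms.items()}
        inv: dict[str, set[str]] = {t: set() for t in (all_terms or [])}
        for g, ts in fwd.items():
            for t in ts:
                inv.setdefault(t, set()).add(g)
        uni = sorted(universe) if universe is not None else sorted(fwd)
        return cls(gene_terms=fwd, term_genes=inv, universe=uni)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]],
                   universe: Iterable[str] | None = None) -> "AnnotationTable":
        fwd: dict[str, set[str]] = {}
        for g, t in pairs:
            fwd.setdefault(g, set()).add(t)
        return cls.from_gene_terms(fwd, universe=universe)

    @property
    def terms(self) -> list[str]:
        return sorted(self.term_genes)


@dataclass
class EnrichmentResult:
    """One module × term overrepresentation test (2×2 table + p/q)."""

    module: int
    term: str
    k: int  # module genes carrying the term
    n: int  # module genes in the universe
    K: int  # universe genes carrying the term
    N: int  # universe size
    p: float
    q: float = float("nan")
    significant: bool = False


@dataclass
class EnrichmentSummary:
    psi1: float
    psi2: float
    psi2_literal: float
    total_significant_terms: int
    n_enriched_modules: int
    n_annotated_modules: int
    alpha: float


def fisher_overrepresentation(k: int, K: int, n: int, N: int) -> float:
    """One-sided upper-tail hypergeometric probability P(X >= k).

    ``k`` module genes carry the term, out of ``n`` module genes, with
    ``K`` carriers in a universe of ``N``. Computed by log-space summation
    of the hypergeometric pmf for numerical stability.
    """
    if not (0 <= k <= min(n, K) <= N and n <= N):
        raise ConfigurationError(
            f"inconsistent contingency counts k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    xs = np.arange(k, min(n, K) + 1)
    log_tail = logsumexp(hypergeom.logpmf(xs, N, K, n))
    return float(min(1.0, math.exp(log_tail)))


_CORRECTIONS = {"fdr_bh": "fdr_bh", "bonferroni": "bonferroni", "none": None}


def enrich_modules(
    partition: Partition,
    annotations: AnnotationTable,
    alpha: float = 0.05,
    correction: str = "fdr_bh",
    min_module_size: int = 5,
) -> list[EnrichmentResult]:
    """Overrepresentation tests for every eligible module × touched term.

    The universe is the intersection of the partition's genes and the
    annotation table's universe. Modules with fewer than
    ``min_module_size`` genes (in the universe) are skipped. Multiple
    testing is corrected within each module; ``significant`` means
    q <= alpha.
    """
    if correction not in _CORRECTIONS:
        raise ConfigurationError(f"unknown correction {correction!r}")
    universe = sorted(set(partition.module_of) & set(annotations.universe))
    if not universe:
        raise ConfigurationError("partition and annotations share no genes")
    uni_set = set(universe)
    N = len(universe)
    term_in_universe = {
        t: gs & uni_set for t, gs in annotations.term_genes.items() if gs & uni_set
    }

    results: list[EnrichmentResult] = []
    for mod_id, members in enumerate(partition.modules):
        mod_genes = set(members) & uni_set
        n = len(mod_genes)
        if n < min_module_size:
            continue
        rows: list[EnrichmentResult] = []
        for term, carriers in sorted(term_in_universe.items()):
            k = len(carriers & mod_genes)
            if k == 0:
                continue
            p = fisher_overrepresentation(k, len(carriers), n, N)
            rows.append(EnrichmentResult(module=mod_id, term=term, k=k, n=n,
                                         K=len(carriers), N=N, p=p))
        if not rows:
            continue
        pvals = np.array([r.p for r in rows])
        method = _CORRECTIONS[correction]
        if method is None:
            qvals = pvals
        else:
            qvals = multipletests(pvals, method=method)[1]
        for r, q in zip(rows, qvals):
            r.q = float(q)
            r.significant = bool(q <= alpha)
        results.extend(rows)
    return results


def psi_summary(
    results: list[EnrichmentResult],
    partition: Partition | None = None,
    alpha: float = 0.05,
) -> EnrichmentSummary:
    """Condense enrichment results into the ψ1/ψ2 statistics.

    ψ1 averages the significant-term count over enriched modules. ψ2
    divides the total number of significant tests by the number of
    annotated modules (default reading); ``psi2_literal`` uses enriched
    modules as the denominator instead.
    """
    sig_per_module: dict[int, int] = {}
    annotated: set[int] = set()
    for r in results:
        annotated.add(r.module)
        if r.significant:
            sig_per_module[r.module] = sig_per_module.get(r.module, 0) + 1
    total_sig = sum(sig_per_module.values())
    n_enriched = len(sig_per_module)
    n_annotated = len(annotated)
    if n_annotated == 0:
        warnings.warn("no module carries an annotated term; psi statistics are 0")
    psi1 = total_sig / n_enriched if n_enriched else 0.0
    psi2 = total_sig / n_annotated if n_annotated else 0.0
    psi2_lit = total_sig / n_enriched if n_enriched else 0.0
    return EnrichmentSummary(
        psi1=psi1,
        psi2=psi2,
        psi2_literal=psi2_lit,
        total_significant_terms=total_sig,
        n_enriched_modules=n_enriched,
        n_annotated_modules=n_annotated,
        alpha=alpha,
    )
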