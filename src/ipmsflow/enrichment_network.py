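"""Hypergeometric over-representation analysis and kappa term networks.

Terms from a gene-set collection are tested for over-representation in a
query gene list against a background universe with the upper-tail
hypergeometric probability, BH-corrected across tested terms.  Significant
terms (raw p < 0.01 by default, matching the ClueGO-style criterion; an
FDR-based cut is available) become nodes of a term network whose edges join
term pairs with Cohen's kappa >= a threshold (default 0.4, inclusive) on
their 2x2 membership table over the query set.  Each term node is also
linked to its query members through a bipartite term-protein layer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from scipy import stats

from statsmodels.stats.multitest import multipletests

from .tables_io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "hypergeom_pvalue",
    "enrich_terms",
    "results_to_frame",
    "top_terms",
    "shared_terms",
    "kappa_score",
    "build_term_network",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-term over-representation statistics.

    k: query genes in the term; K: universe genes in the term; n: query
    size; N: universe size.
    """

    term_id: str
    term_name: str
    category: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    fdr: float
    enriched: bool

    def __post_init__(self):
        if not (0 <= self.k <= min(self.K, self.n) and self.K <= self.N
                and self.n <= self.N):
            raise ValueError(
                f"term {self.term_id}: inconsistent counts "
                f"k={self.k}, K={self.K}, n={self.n}, N={self.N}")

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p_value) if self.p_value > 0 else math.inf


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P[X >= k] for X ~ Hypergeometric(N, K, n).

    The probability that a size-``n`` draw from a universe of ``N`` genes, of
    which ``K`` carry the annotation, contains at least ``k`` annotated
    genes.  Computed through scipy's survival function, which works in log
    space internally and is numerically stable for extreme tails.
    """
    if min(k, K, n, N) < 0:
        raise ValueError("counts must be non-negative")
    if not (k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_terms(query: Iterable[str], collection: GeneSetCollection,
                 universe: Iterable[str], alpha: float = 0.01,
                 use_fdr: bool = False) -> list[EnrichmentResult]:
    """Test every term of ``collection`` for over-representation in ``query``.

    The query must be a subset of the universe; term memberships are
    intersected with the universe before counting.  ``enriched`` is
    ``p < alpha`` (or ``fdr < alpha`` with ``use_fdr``); the BH FDR over all
    tested terms is always reported.
    """
    query = set(query)
    universe = set(universe)
    if not universe or not query:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValueError(f"query is not a subset of the universe (e.g. {extra})")
    N, n = len(universe), len(query)
    rows = []
    for term in collection:
        members = term.members & universe
        K = len(members)
        k = len(members & query)
        p = hypergeom_pvalue(k, K, n, N)
        rows.append((term, k, K, p))
    pvals = [r[3] for r in rows]
    fdrs = multipletests(pvals, method="fdr_bh")[1] if rows else []
    results = []
    for (term, k, K, p), fdr in zip(rows, fdrs):
        crit = fdr if use_fdr else p
        results.append(EnrichmentResult(
            term_id=term.term_id, term_name=term.name, category=term.category,
            k=k, K=K, n=n, N=N, p_value=p, fdr=float(fdr),
            enriched=bool(crit < alpha)))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    cols = ["term_id", "term_name", "category", "k", "K", "n", "N",
            "p_value", "fdr", "enriched"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results],
                        columns=cols)


def top_terms(results: Sequence[EnrichmentResult], m: int) -> list[EnrichmentResult]:
    """The ``m`` most significant terms: ascending p, ties by descending k,
    then term_id lexicographic."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > len(results):
        logger.warning("requested top %d of %d results; returning all",
                       m, len(results))
    ranked = sorted(results, key=lambda r: (r.p_value, -r.k, r.term_id))
    return ranked[:m]


def shared_terms(results_a: Sequence[EnrichmentResult],
                 results_b: Sequence[EnrichmentResult], m: int) -> set[str]:
    """Term ids common to the top-``m`` lists of two analyses."""
    top_a = {r.term_id for r in top_terms(results_a, m)}
    top_b = {r.term_id for r in top_terms(results_b, m)}
    return top_a & top_b


def kappa_score(members_a: Iterable[str], members_b: Iterable[str],
                universe: Iterable[str]) -> float:
    """Cohen's kappa of two gene sets' membership over a universe.

    With a = |A∩B|, b = |A\\B|, c = |B\\A|, d = |universe \\ (A∪B)| and
    N = a+b+c+d: observed agreement Po = (a+d)/N, chance agreement
    Pe = ((a+b)(a+c) + (c+d)(b+d))/N**2, kappa = (Po-Pe)/(1-Pe); by
    convention kappa = 1 when Pe = 1 (both marginals degenerate).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("kappa universe must be non-empty")
    A = set(members_a) & universe
    B = set(members_b) & universe
    n = len(universe)
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = n - a - b - c
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n ** 2
    if pe >= 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


def build_term_network(results: Sequence[EnrichmentResult],
                       collection: GeneSetCollection,
                       query: Iterable[str],
                       kappa_threshold: float = 0.4,
                       kappa_universe: Iterable[str] | None = None) -> nx.Graph:
    """Build the term / term-protein network from enriched terms.

    Nodes are the ``enriched`` results (attributes: p_value, fdr, size =
    query genes in the term, neg_log10_p as the node-size proxy).  A kappa
    edge joins two terms when Cohen's kappa of their query-restricted member
    sets over the query universe is >= ``kappa_threshold`` (inclusive), with
    the kappa value as edge weight.  Each query member of a term is added as
    a small protein node joined to the term (bipartite layer), so every
    protein node touches at least one term.

    ``kappa_universe`` defaults to the query set (overlap among the
    identified proteins); pass the annotation universe for the alternative
    convention.
    """
    query = set(query)
    g = nx.Graph()
    enriched = [r for r in results if r.enriched]
    universe = set(kappa_universe) if kappa_universe is not None else query
    overlap: dict[str, set[str]] = {}
    for r in enriched:
        members = collection[r.term_id].members & query
        overlap[r.term_id] = members
        g.add_node(r.term_id, kind="term", term_name=r.term_name,
                   category=r.category, p_value=r.p_value, fdr=r.fdr,
                   size=len(members), neg_log10_p=float(r.neg_log10_p))
    ordered = sorted(overlap)
    for i, ti in enumerate(ordered):
        for tj in ordered[i + 1:]:
            kap = kappa_score(overlap[ti], overlap[tj], universe)
            if kap >= kappa_threshold:
                g.add_edge(ti, tj, kind="kappa", kappa=float(kap))
    for term_id, members in overlap.items():
        for gene in sorted(members):
            node = f"protein:{gene}"
            if node not in g:
                g.add_node(node, kind="protein", gene_symbol=gene)
            g.add_edge(term_id, node, kind="membership")
    return g
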