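"""Enrichment-map construction.

Gene sets surviving the q-value filter become nodes; any two nodes
whose member overlap (Jaccard coefficient, computed on the sets
restricted to the ranked universe by default) reaches the similarity
threshold are connected.  Both thresholds keep/connect on the
boundary: ``q <= q_max`` keeps a node and ``similarity >= similarity_min``
adds an edge.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx

from .datatypes import (
    EnrichmentNetwork,
    EnrichmentResult,
    GeneSetDatabase,
    RankedList,
)

__all__ = ["NetworkParams", "filter_significant", "jaccard", "build_network"]


@dataclass(frozen=True)
class NetworkParams:
    """Node and edge thresholds of the enrichment map."""

    q_max: float = 0.0001
    similarity_min: float = 0.5
    similarity_metric: str = "jaccard"
    restrict_to_universe: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.q_max <= 1):
            raise ValueError("q_max must be in (0, 1]")
        if not (0 < self.similarity_min <= 1):
            raise ValueError("similarity_min must be in (0, 1]")
        if self.similarity_metric != "jaccard":
            raise ValueError(
                f"unknown similarity metric {self.similarity_metric!r}"
            )


def filter_significant(
    results: Sequence[EnrichmentResult], q_max: float = 0.0001
) -> list[EnrichmentResult]:
    """Retain exactly the results with ``q_value <= q_max`` (order kept)."""
    return [r for r in results if r.q_value <= q_max]


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """Jaccard coefficient |a n b| / |a u b|."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        raise ValueError("Jaccard similarity of two empty sets is undefined")
    return len(sa & sb) / len(union)


def build_network(
    results: Sequence[EnrichmentResult],
    db: GeneSetDatabase,
    ranks: RankedList,
    params: NetworkParams = NetworkParams(),
) -> EnrichmentNetwork:
    """Connect significant gene sets by member overlap.

    One node per result (attributes ``nes``, ``padj``, ``size``); an
    edge for every unordered pair with Jaccard similarity at or above
    the threshold, carrying ``similarity`` and ``overlap_size``.  Node
    and edge ordering is lexicographic, so the construction is
    deterministic.
    """
    missing = [r.set_name for r in results if r.set_name not in db]
    if missing:
        raise ValueError(f"result sets missing from database: {missing}")
    universe = set(ranks.genes)
    members: dict[str, frozenset[str]] = {}
    by_name = {r.set_name: r for r in results}
    for name in by_name:
        m = db[name].members
        if params.restrict_to_universe:
            m = frozenset(g for g in m if g in universe)
        members[name] = m
    graph = nx.Graph()
    for name in sorted(by_name):
        r = by_name[name]
        graph.add_node(
            name, nes=r.nes, padj=r.q_value, size=r.size, cluster=None
        )
    for u, v in combinations(sorted(by_name), 2):
        mu, mv = members[u], members[v]
        if not mu and not mv:
            continue
        overlap = len(mu & mv)
        sim = overlap / len(mu | mv)
        if sim >= params.similarity_min:
            graph.add_edge(u, v, similarity=sim, overlap_size=overlap)
    return EnrichmentNetwork(graph=graph, clusters=None)
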