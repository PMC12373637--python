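"""Clustering and labelling of the enrichment map.

The default clustering is the minimal faithful reading of "groups of
highly overlapping pathways": connected components of the thresholded
similarity graph.  Greedy modularity communities on similarity-weighted
edges are available for dense maps.  Each cluster gets a short label
from the most frequent words of its member set names, after dropping a
small shipped stop-word list (common English function words plus
generic pathway-nomenclature words).
"""
from __future__ import annotations

import re
from collections import Counter
from typing import Iterable

import networkx as nx

from .datatypes import Cluster, EnrichmentNetwork

__all__ = ["DEFAULT_STOPWORDS", "cluster_network", "label_cluster", "annotate"]

DEFAULT_STOPWORDS: frozenset[str] = frozenset(
    {
        # English function words
        "a", "an", "and", "at", "by", "for", "from", "in", "into", "of",
        "on", "or", "the", "to", "via", "with",
        # generic pathway-nomenclature words
        "pathway", "pathways", "process", "processes", "regulation",
        "gene", "genes", "positive", "negative",
        # database prefixes that leak into set names
        "go", "gobp", "kegg", "reactome", "wikipathways", "wp", "hsa",
    }
)

_TOKEN_SPLIT = re.compile(r"[^0-9A-Za-z]+")

_MAX_SINGLETON_LABEL = 60


def cluster_network(
    net: EnrichmentNetwork, method: str = "components"
) -> list[Cluster]:
    """Partition the network nodes into clusters.

    ``components`` (default) takes connected components of the
    thresholded similarity graph; ``modularity`` runs greedy modularity
    communities with edge ``similarity`` as weight.  Singleton nodes
    form singleton clusters.  Cluster ids are assigned in decreasing
    size order (ties: lexicographically smallest member), starting at
    1, and written back onto the network (``net.clusters`` and the
    ``cluster`` node attribute).
    """
    g = net.graph
    if method == "components":
        groups: list[set[str]] = [set(c) for c in nx.connected_components(g)]
    elif method == "modularity":
        if g.number_of_nodes() == 0:
            groups = []
        else:
            groups = [
                set(c)
                for c in nx.algorithms.community.greedy_modularity_communities(
                    g, weight="similarity"
                )
            ]
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    ordered = sorted(groups, key=lambda c: (-len(c), min(c)))
    clusters = [
        Cluster(id=i, members=tuple(sorted(c)))
        for i, c in enumerate(ordered, start=1)
    ]
    assignment = {
        name: c.id for c in clusters for name in c.members
    }
    net.clusters = assignment
    for name, cid in assignment.items():
        g.nodes[name]["cluster"] = cid
    return clusters


def label_cluster(
    cluster: Cluster,
    net: EnrichmentNetwork | None = None,
    stopwords: Iterable[str] = DEFAULT_STOPWORDS,
) -> str:
    """Short text label from member set-name word frequencies.

    Tokenizes set names on non-alphanumerics, lowercases, drops
    stop words and pure numbers, and joins the top three words by
    frequency (ties broken alphabetically).  A singleton cluster is
    labelled with its own set name, truncated to 60 characters; an
    empty token pool falls back to the first member name.
    """
    stop = set(stopwords)
    if len(cluster.members) == 1:
        return cluster.members[0][:_MAX_SINGLETON_LABEL]
    counts: Counter[str] = Counter()
    for name in cluster.members:
        tokens = [
            t.lower()
            for t in _TOKEN_SPLIT.split(name)
            if t and not t.isdigit() and t.lower() not in stop
        ]
        counts.update(tokens)
    if not counts:
        return cluster.members[0]
    top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:3]
    return " ".join(word for word, _ in top)


def annotate(
    net: EnrichmentNetwork,
    method: str = "components",
    stopwords: Iterable[str] = DEFAULT_STOPWORDS,
) -> list[Cluster]:
    """Cluster the network and attach a label to every cluster."""
    clusters = cluster_network(net, method=method)
    labelled = [
        Cluster(id=c.id, members=c.members, label=label_cluster(c, net, stopwords))
        for c in clusters
    ]
    for c in labelled:
        for name in c.members:
            net.graph.nodes[name]["cluster_label"] = c.label
    return labelled
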