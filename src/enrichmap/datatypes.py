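"""Core data containers shared across the pipeline.

Gene identifiers are normalized at parse time so that expression tables,
RNK files, and GMT databases join reliably: HGNC symbols are upper-cased
and Ensembl identifiers have their version suffix (``.N``) stripped.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "normalize_gene_id",
    "GeneSet",
    "GeneSetDatabase",
    "RankedList",
    "ExpressionMatrix",
    "EnrichmentResult",
    "EnrichmentNetwork",
    "Cluster",
]

_ENSEMBL_VERSIONED = re.compile(r"(ENS[A-Z]*\d{6,})\.\d+")


def normalize_gene_id(gene: str) -> str:
    """Canonical form of a gene identifier.

    Symbols are upper-cased; Ensembl IDs additionally lose their version
    suffix (``ENSG00000141510.11`` -> ``ENSG00000141510``).
    """
    g = gene.strip().upper()
    m = _ENSEMBL_VERSIONED.fullmatch(g)
    if m:
        return m.group(1)
    return g


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers (e.g. one GMT line)."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)


class GeneSetDatabase:
    """An ordered collection of uniquely named :class:`GeneSet` objects."""

    def __init__(self, sets: Iterable[GeneSet], source: str = "") -> None:
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.name in self._sets:
                raise ValueError(f"duplicate gene set name {s.name!r}")
            self._sets[s.name] = s
        self.source = source

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __contains__(self, name: object) -> bool:
        return name in self._sets

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetDatabase):
            return NotImplemented
        return list(self) == list(other)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GeneSetDatabase({len(self)} sets, source={self.source!r})"


class RankedList:
    """Genes with signed real scores, ordered by decreasing score.

    Ties in score are broken by ascending gene identifier so that the
    ordering is a deterministic function of the (gene, score) pairs.
    """

    def __init__(self, pairs: Iterable[tuple[str, float]]) -> None:
        seen: dict[str, float] = {}
        for gene, score in pairs:
            s = float(score)
            if not np.isfinite(s):
                raise ValueError(f"non-finite score for gene {gene!r}")
            if gene in seen:
                raise ValueError(f"duplicate gene {gene!r} in ranked list")
            seen[gene] = s
        if not seen:
            raise ValueError("ranked list is empty")
        ordered = sorted(seen.items(), key=lambda kv: (-kv[1], kv[0]))
        self._genes: tuple[str, ...] = tuple(g for g, _ in ordered)
        self._scores: np.ndarray = np.array([s for _, s in ordered], dtype=float)
        self._scores.flags.writeable = False
        self._index: dict[str, int] = {g: i for i, g in enumerate(self._genes)}

    @property
    def genes(self) -> tuple[str, ...]:
        return self._genes

    @property
    def scores(self) -> np.ndarray:
        return self._scores

    def position(self, gene: str) -> int:
        return self._index[gene]

    def __contains__(self, gene: object) -> bool:
        return gene in self._index

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(zip(self._genes, self._scores.tolist()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RankedList):
            return NotImplemented
        return self._genes == other._genes and np.array_equal(
            self._scores, other._scores
        )

    def as_series(self) -> pd.Series:
        return pd.Series(self._scores, index=list(self._genes), name="score")


class ExpressionMatrix:
    """A genes x samples matrix of non-negative counts with two-class labels.

    ``counts`` is a pandas DataFrame (rows = genes, columns = samples).
    ``classes`` maps every sample to one of exactly two class labels; the
    lexicographically smaller label is treated as the reference class "A"
    and fold changes are reported as B vs A.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        classes: Mapping[str, str] | None = None,
    ) -> None:
        if counts.shape[0] == 0 or counts.shape[1] == 0:
            raise ValueError("expression matrix is empty")
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier {dup!r}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample name {dup!r}")
        values = counts.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("expression matrix contains non-finite values")
        if (values < 0).any():
            gene = counts.index[np.where(values < 0)[0][0]]
            raise ValueError(f"negative count for gene {gene!r}")
        self.counts = counts.astype(float)
        self.classes: dict[str, str] | None = None
        if classes is not None:
            self._set_classes(dict(classes))

    def _set_classes(self, classes: dict[str, str]) -> None:
        missing = [s for s in self.samples if s not in classes]
        if missing:
            raise ValueError(f"samples without class assignment: {missing}")
        labels = sorted(set(classes[s] for s in self.samples))
        if len(labels) != 2:
            raise ValueError(
                f"exactly two class labels required, got {labels}"
            )
        self.classes = {s: classes[s] for s in self.samples}

    def with_classes(self, classes: Mapping[str, str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.counts, classes)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.counts.index)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.counts.columns)

    @property
    def class_labels(self) -> tuple[str, str]:
        if self.classes is None:
            raise ValueError("class assignment not set")
        labels = sorted(set(self.classes.values()))
        return (labels[0], labels[1])

    def class_samples(self, label: str) -> tuple[str, ...]:
        if self.classes is None:
            raise ValueError("class assignment not set")
        return tuple(s for s in self.samples if self.classes[s] == label)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.counts.loc[list(genes)], self.classes)


@dataclass(frozen=True)
class EnrichmentResult:
    """Preranked GSEA statistics for one gene set."""

    set_name: str
    size: int
    es: float
    nes: float
    p_value: float
    q_value: float
    leading_edge: tuple[str, ...]
    flags: tuple[str, ...] = ()


@dataclass
class EnrichmentNetwork:
    """Enrichment map: significant gene sets joined by member overlap.

    Nodes carry ``nes``, ``padj``, ``size`` and (after clustering)
    ``cluster``; edges carry ``similarity`` and ``overlap_size``.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    clusters: dict[str, int] | None = None

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(self.graph.nodes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EnrichmentNetwork):
            return NotImplemented
        return (
            dict(self.graph.nodes(data=True)) == dict(other.graph.nodes(data=True))
            and nx.utils.graphs_equal(self.graph, other.graph)
            and self.clusters == other.clusters
        )


@dataclass(frozen=True)
class Cluster:
    """A group of network nodes with a short descriptive label."""

    id: int
    members: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster has no members")
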