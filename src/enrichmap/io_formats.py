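"""Readers and writers for the standard formats the pipeline touches.

Formats: GMT gene-set databases, RNK ranked gene lists, TSV/CSV expression
tables, TSV enrichment-result tables, JSON/GraphML network files, and a
three-file enrichment folder suitable for downstream network tools.

All readers reject structural violations (duplicates, negative counts,
non-numeric fields) instead of silently repairing them.  Numeric output
uses full ``repr`` precision with a ``.`` decimal separator so that
exports round-trip bit-stably.
"""
from __future__ import annotations

import csv
import json
import os
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    EnrichmentNetwork,
    EnrichmentResult,
    ExpressionMatrix,
    GeneSet,
    GeneSetDatabase,
    RankedList,
    normalize_gene_id,
)

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_rnk",
    "write_rnk",
    "read_expression",
    "write_expression",
    "write_results_tsv",
    "read_results_tsv",
    "write_network",
    "read_network_json",
    "export_enrichment_folder",
]

NETWORK_FORMAT_VERSION = 1

RESULT_COLUMNS = ("name", "size", "es", "nes", "pval", "padj", "leading_edge")

ENRICHMENT_FOLDER_FILES = {
    "results": "enrichment_results.tsv",
    "ranks": "ranks.rnk",
    "gmt": "gene_sets.gmt",
}


def _fmt(x: float) -> str:
    """Full-precision decimal rendering (>= 17 significant digits)."""
    return repr(float(x))


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetDatabase:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Gene symbols are upper-cased and duplicates within a line collapsed.
    Lines with fewer than three fields and duplicate set names are errors.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    names: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: GMT line has {len(fields)} field(s), "
                    "expected name, description and at least one gene"
                )
            name, description = fields[0], fields[1]
            if name in names:
                raise ValueError(
                    f"{path.name}:{lineno}: duplicate gene set name {name!r}"
                )
            members = frozenset(
                normalize_gene_id(g) for g in fields[2:] if g.strip()
            )
            if not members:
                raise ValueError(
                    f"{path.name}:{lineno}: gene set {name!r} has no genes"
                )
            names.add(name)
            sets.append(GeneSet(name=name, description=description, members=members))
    return GeneSetDatabase(sets, source=str(path))


def write_gmt(db: GeneSetDatabase, path: str | Path) -> None:
    """Write a database in the same GMT dialect :func:`read_gmt` expects.

    Members are written in sorted order so output is deterministic and
    ``read_gmt(write_gmt(db)) == db``.
    """
    if len(db) == 0:
        raise ValueError("refusing to write an empty gene set database")
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for s in db:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# RNK
# ---------------------------------------------------------------------------

def read_rnk(path: str | Path) -> RankedList:
    """Parse a GSEA RNK file (``gene<TAB>score``; ``#`` comments allowed).

    The list is re-sorted by descending score regardless of file order,
    with lexicographic tie-breaking.  Duplicate genes and non-finite
    scores are errors.
    """
    path = Path(path)
    pairs: list[tuple[str, float]] = []
    seen: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path.name}:{lineno}: expected gene<TAB>score, "
                    f"got {len(fields)} field(s)"
                )
            gene = normalize_gene_id(fields[0])
            try:
                score = float(fields[1])
            except ValueError:
                raise ValueError(
                    f"{path.name}:{lineno}: score {fields[1]!r} is not numeric"
                ) from None
            if not np.isfinite(score):
                raise ValueError(
                    f"{path.name}:{lineno}: score for gene {gene!r} is not finite"
                )
            if gene in seen:
                raise ValueError(f"{path.name}:{lineno}: duplicate gene {gene!r}")
            seen.add(gene)
            pairs.append((gene, score))
    return RankedList(pairs)


def write_rnk(ranks: RankedList, path: str | Path) -> None:
    """Write a ranked list as a two-column RNK file (descending score)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for gene, score in ranks:
            fh.write(f"{gene}\t{_fmt(score)}\n")


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def _detect_delimiter(path: Path, delimiter: str) -> str:
    if delimiter == "tab":
        return "\t"
    if delimiter == "comma":
        return ","
    if delimiter != "auto":
        raise ValueError(f"unknown delimiter token {delimiter!r}")
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return ","
    if suffix in (".tsv", ".txt", ".tab"):
        return "\t"
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
    return "," if first.count(",") > first.count("\t") else "\t"


def read_expression(path: str | Path, delimiter: str = "auto") -> ExpressionMatrix:
    """Read a genes x samples count table (TSV or CSV; classes unset).

    First row is the header of sample names; first column holds gene
    identifiers.  Ragged rows, duplicate genes or samples, negative or
    non-numeric values, and empty matrices are errors.
    """
    path = Path(path)
    sep = _detect_delimiter(path, delimiter)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        rows = [row for row in reader if row and any(f.strip() for f in row)]
    if not rows:
        raise ValueError(f"{path.name}: empty expression file")
    header = rows[0]
    samples = [s.strip() for s in header[1:]]
    if not samples:
        raise ValueError(f"{path.name}: no sample columns in header")
    if len(set(samples)) != len(samples):
        dup = next(s for i, s in enumerate(samples) if s in samples[:i])
        raise ValueError(f"{path.name}: duplicate sample name {dup!r}")
    genes: list[str] = []
    seen: set[str] = set()
    data = np.empty((len(rows) - 1, len(samples)), dtype=float)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ValueError(
                f"{path.name}:{i}: ragged row ({len(row)} fields, "
                f"expected {len(header)})"
            )
        gene = normalize_gene_id(row[0])
        if gene in seen:
            raise ValueError(f"{path.name}:{i}: duplicate gene row {gene!r}")
        seen.add(gene)
        genes.append(gene)
        for j, val in enumerate(row[1:]):
            try:
                x = float(val)
            except ValueError:
                raise ValueError(
                    f"{path.name}:{i}: value {val!r} for gene {gene!r} "
                    "is not numeric"
                ) from None
            if not np.isfinite(x):
                raise ValueError(
                    f"{path.name}:{i}: non-finite value for gene {gene!r}"
                )
            if x < 0:
                raise ValueError(
                    f"{path.name}:{i}: negative count for gene {gene!r}"
                )
            data[i - 2, j] = x
    if not genes:
        raise ValueError(f"{path.name}: no gene rows")
    counts = pd.DataFrame(data, index=genes, columns=samples)
    return ExpressionMatrix(counts)


def write_expression(x: ExpressionMatrix, path: str | Path, delimiter: str = "tab") -> None:
    """Write a count matrix as TSV (default) or CSV with a ``gene`` header."""
    sep = {"tab": "\t", "comma": ","}.get(delimiter)
    if sep is None:
        raise ValueError(f"unknown delimiter token {delimiter!r}")
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(sep.join(["gene", *x.samples]) + "\n")
        values = x.counts.to_numpy()
        for gene, row in zip(x.genes, values):
            fh.write(sep.join([gene, *(_fmt(v) for v in row)]) + "\n")


# ---------------------------------------------------------------------------
# Enrichment result tables
# ---------------------------------------------------------------------------

def write_results_tsv(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    """Write enrichment results as TSV with a fixed, stable column order."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.set_name,
                        str(r.size),
                        _fmt(r.es),
                        _fmt(r.nes),
                        _fmt(r.p_value),
                        _fmt(r.q_value),
                        ",".join(r.leading_edge),
                    ]
                )
                + "\n"
            )


def read_results_tsv(path: str | Path) -> list[EnrichmentResult]:
    """Read a result table written by :func:`write_results_tsv`."""
    path = Path(path)
    results: list[EnrichmentResult] = []
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != RESULT_COLUMNS:
            raise ValueError(f"{path.name}: unexpected result columns {header}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != len(RESULT_COLUMNS):
                raise ValueError(f"{path.name}:{lineno}: ragged result row")
            leading = tuple(g for g in f[6].split(",") if g)
            results.append(
                EnrichmentResult(
                    set_name=f[0],
                    size=int(f[1]),
                    es=float(f[2]),
                    nes=float(f[3]),
                    p_value=float(f[4]),
                    q_value=float(f[5]),
                    leading_edge=leading,
                )
            )
    return results


# ---------------------------------------------------------------------------
# Network files
# ---------------------------------------------------------------------------

def _node_record(name: str, data: dict) -> dict:
    return {
        "name": name,
        "nes": data.get("nes"),
        "padj": data.get("padj"),
        "size": data.get("size"),
        "cluster": data.get("cluster"),
    }


def write_network(net: EnrichmentNetwork, path: str | Path, format: str = "json") -> None:
    """Write the enrichment network as versioned JSON or GraphML.

    JSON schema (version 1)::

        {"format": "enrichment-network", "version": 1,
         "nodes": [{"name", "nes", "padj", "size", "cluster"}, ...],
         "edges": [{"source", "target", "similarity", "overlap_size"}, ...]}
    """
    path = Path(path)
    g = net.graph
    if format == "json":
        doc = {
            "format": "enrichment-network",
            "version": NETWORK_FORMAT_VERSION,
            "nodes": [_node_record(n, d) for n, d in g.nodes(data=True)],
            "edges": [
                {
                    "source": u,
                    "target": v,
                    "similarity": d.get("similarity"),
                    "overlap_size": d.get("overlap_size"),
                }
                for u, v, d in g.edges(data=True)
            ],
        }
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            json.dump(doc, fh, indent=2, sort_keys=False)
            fh.write("\n")
    elif format == "graphml":
        out = nx.Graph()
        for n, d in g.nodes(data=True):
            attrs = {k: v for k, v in _node_record(n, d).items() if v is not None}
            attrs.pop("name", None)
            out.add_node(n, **attrs)
        for u, v, d in g.edges(data=True):
            out.add_edge(u, v, similarity=d["similarity"], overlap_size=d["overlap_size"])
        nx.write_graphml(out, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_json(path: str | Path) -> EnrichmentNetwork:
    """Read a version-1 JSON network file back into memory."""
    with Path(path).open("r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format") != "enrichment-network":
        raise ValueError("not an enrichment-network JSON file")
    if doc.get("version") != NETWORK_FORMAT_VERSION:
        raise ValueError(f"unsupported network format version {doc.get('version')}")
    g = nx.Graph()
    clusters: dict[str, int] = {}
    for nd in doc["nodes"]:
        g.add_node(nd["name"], nes=nd["nes"], padj=nd["padj"], size=nd["size"],
                   cluster=nd["cluster"])
        if nd["cluster"] is not None:
            clusters[nd["name"]] = nd["cluster"]
    for ed in doc["edges"]:
        g.add_edge(ed["source"], ed["target"], similarity=ed["similarity"],
                   overlap_size=ed["overlap_size"])
    return EnrichmentNetwork(graph=g, clusters=clusters or None)


# ---------------------------------------------------------------------------
# Enrichment folder
# ---------------------------------------------------------------------------

def export_enrichment_folder(
    results: Sequence[EnrichmentResult],
    ranks: RankedList,
    db: GeneSetDatabase,
    directory: str | Path,
    overwrite: bool = False,
) -> Path:
    """Write a three-file enrichment folder.

    Layout: ``enrichment_results.tsv`` (the result table), ``ranks.rnk``
    (the ranked list), and ``gene_sets.gmt`` (only the sets present in
    the results).  A non-empty target directory is an error unless
    ``overwrite`` is given.
    """
    directory = Path(directory)
    if directory.exists():
        if not directory.is_dir():
            raise ValueError(f"{directory} exists and is not a directory")
        if any(directory.iterdir()) and not overwrite:
            raise FileExistsError(
                f"directory {directory} is not empty (pass overwrite=True)"
            )
    else:
        directory.mkdir(parents=True)
    write_results_tsv(results, directory / ENRICHMENT_FOLDER_FILES["results"])
    write_rnk(ranks, directory / ENRICHMENT_FOLDER_FILES["ranks"])
    names = [r.set_name for r in results]
    missing = [n for n in names if n not in db]
    if missing:
        raise ValueError(f"result sets missing from database: {missing}")
    gmt_path = directory / ENRICHMENT_FOLDER_FILES["gmt"]
    if names:
        filtered = GeneSetDatabase((db[n] for n in names), source=db.source)
        write_gmt(filtered, gmt_path)
    else:
        gmt_path.write_text("", encoding="utf-8")
    return directory
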