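"""Self-contained synthetic fixtures for every pipeline stage.

Counts follow a negative binomial model with variance ``mu + a*mu**2``
(the same parameterization the differential test assumes): per-gene
relative abundances are log-normal, per-sample library sizes are drawn
uniformly from a range, and a planted fraction of genes receives a
known +/- log2 fold change in class B with balanced signs.  Applying
fold changes without renormalizing the columns also plants the
composition bias that TMM normalization is designed to remove.

Gene-set databases contain planted enriched sets (drawing at least 60%
of their members from same-sign differentially expressed genes),
uniform decoy sets over the non-DE genes, and groups of highly
overlapping enriched sets built by perturbing a seed set, to exercise
network clustering.  Every fixture is reproducible byte-for-byte from
its parameters and seed.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSet, GeneSetDatabase
from . import io_formats

__all__ = [
    "SimulationTruth",
    "simulate_counts",
    "simulate_genesets",
    "write_fixtures",
]

#: Minimum fraction of enriched-set members drawn from same-sign DE genes.
DE_MEMBER_FRACTION = 0.6

#: Log-normal parameters of per-gene relative abundance (natural log scale).
ABUNDANCE_MEANLOG = 4.5
ABUNDANCE_SDLOG = 1.2


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth planted by the generators.

    ``de_genes`` maps gene -> true log2 fold change (class B vs A);
    ``enriched_sets`` maps set name -> expected NES sign (+1/-1);
    ``planted_clusters`` lists the groups of set names intended to
    co-cluster; ``genes`` is the simulated gene universe.
    """

    de_genes: dict[str, float] = field(default_factory=dict)
    enriched_sets: dict[str, int] = field(default_factory=dict)
    planted_clusters: tuple[tuple[str, ...], ...] = ()
    seed: int = 0
    genes: tuple[str, ...] = ()

    def to_json(self, path: str | Path) -> None:
        doc = {
            "de_genes": self.de_genes,
            "enriched_sets": self.enriched_sets,
            "planted_clusters": [list(g) for g in self.planted_clusters],
            "seed": self.seed,
            "genes": list(self.genes),
        }
        with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        with Path(path).open("r", encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(
            de_genes={g: float(v) for g, v in doc["de_genes"].items()},
            enriched_sets={n: int(v) for n, v in doc["enriched_sets"].items()},
            planted_clusters=tuple(tuple(g) for g in doc["planted_clusters"]),
            seed=int(doc["seed"]),
            genes=tuple(doc["genes"]),
        )


def simulate_counts(
    n_genes: int = 10_000,
    n_per_class: int = 3,
    dispersion: float = 0.1,
    lib_size_range: tuple[float, float] = (1.0e6, 2.0e6),
    de_fraction: float = 0.1,
    lfc: float = 2.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Negative-binomial count matrix with planted differential expression."""
    if n_genes < 100:
        raise ValueError("n_genes must be at least 100")
    if n_per_class < 2:
        raise ValueError("n_per_class must be at least 2")
    if not (0 <= de_fraction < 1):
        raise ValueError("de_fraction must be in [0, 1)")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    lo, hi = lib_size_range
    if not (0 < lo <= hi):
        raise ValueError("invalid library size range")
    if lfc < 0:
        raise ValueError("lfc must be non-negative")

    rng = np.random.default_rng(seed)
    genes = tuple(f"G{i:05d}" for i in range(1, n_genes + 1))
    abundance = rng.lognormal(ABUNDANCE_MEANLOG, ABUNDANCE_SDLOG, size=n_genes)
    base_frac = abundance / abundance.sum()

    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    signs = np.ones(n_de)
    signs[n_de // 2 :] = -1.0  # balanced up/down (one extra up when odd)
    true_lfc = np.zeros(n_genes)
    true_lfc[de_idx] = signs * lfc

    n_samples = 2 * n_per_class
    lib_sizes = rng.uniform(lo, hi, size=n_samples)
    fold = np.ones((n_genes, n_samples))
    fold[:, n_per_class:] = 2.0 ** true_lfc[:, None]
    mu = base_frac[:, None] * lib_sizes[None, :] * fold
    if dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))

    samples = [f"A{i + 1}" for i in range(n_per_class)] + [
        f"B{i + 1}" for i in range(n_per_class)
    ]
    classes = {s: ("A" if s.startswith("A") else "B") for s in samples}
    matrix = ExpressionMatrix(
        pd.DataFrame(counts.astype(float), index=list(genes), columns=samples),
        classes,
    )
    truth = SimulationTruth(
        de_genes={genes[i]: float(true_lfc[i]) for i in de_idx},
        seed=seed,
        genes=genes,
    )
    return matrix, truth


def _max_swap(size: int, intra_overlap: float) -> int:
    """Largest per-set member swap keeping pairwise Jaccard >= intra_overlap.

    Two variants that each replace r members of a common seed share at
    least ``size - 2r`` members over a union of at most ``size + 2r``.
    """
    r = math.floor(size * (1 - intra_overlap) / (2 * (1 + intra_overlap)))
    return max(r, 0)


def _pairwise_jaccard_ok(
    sets: list[frozenset[str]], threshold: float, at_least: bool
) -> bool:
    for a, b in combinations(sets, 2):
        j = len(a & b) / len(a | b)
        if at_least and j < threshold:
            return False
        if not at_least and j >= threshold:
            return False
    return True


def simulate_genesets(
    truth: SimulationTruth,
    n_enriched: int = 5,
    n_decoy: int = 200,
    size_range: tuple[int, int] = (20, 60),
    n_cluster_groups: int = 2,
    intra_overlap: float = 0.6,
    seed: int = 0,
    enriched_set_size: int = 30,
    max_retries: int = 20,
) -> tuple[GeneSetDatabase, SimulationTruth]:
    """GMT database with planted enriched, decoy, and overlapping sets.

    Enriched sets are organized into ``n_cluster_groups`` groups of
    highly overlapping sets (alternating expected NES sign by group);
    within a group the sets are perturbations of a common seed set, so
    pairwise Jaccard stays at or above ``intra_overlap`` while
    different groups stay below 0.5.  Decoys sample uniformly from the
    non-DE genes with sizes uniform in ``size_range``.
    """
    if not truth.genes:
        raise ValueError("truth carries no gene universe")
    if n_enriched < 0 or n_decoy < 0:
        raise ValueError("set counts must be non-negative")
    if n_cluster_groups > max(n_enriched, 0) and n_enriched > 0:
        raise ValueError("more cluster groups than enriched sets")
    lo, hi = size_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid decoy size range")
    if not (0 < intra_overlap < 1):
        raise ValueError("intra_overlap must be in (0, 1)")

    rng = np.random.default_rng(seed)
    up = sorted(g for g, l in truth.de_genes.items() if l > 0)
    down = sorted(g for g, l in truth.de_genes.items() if l < 0)
    de = set(truth.de_genes)
    non_de = sorted(g for g in truth.genes if g not in de)

    n_de_members = math.ceil(DE_MEMBER_FRACTION * enriched_set_size)
    n_fill = enriched_set_size - n_de_members

    sets: list[GeneSet] = []
    enriched: dict[str, int] = {}
    groups_out: list[tuple[str, ...]] = []

    if n_enriched > 0:
        group_sizes = [len(chunk) for chunk in np.array_split(np.arange(n_enriched), n_cluster_groups or 1)]
        group_sizes = [g for g in group_sizes if g > 0]
        r_swap = _max_swap(enriched_set_size, intra_overlap)
        for gi, gsize in enumerate(group_sizes):
            sign = 1 if gi % 2 == 0 else -1
            pool = up if sign > 0 else down
            if len(pool) < n_de_members:
                raise ValueError(
                    f"not enough {'up' if sign > 0 else 'down'}-regulated DE "
                    f"genes ({len(pool)}) for an enriched set of "
                    f"{n_de_members} DE members"
                )
            if gsize > 1 and r_swap < 1:
                raise ValueError(
                    "intra_overlap too strict: cannot perturb sets while "
                    "keeping them distinct"
                )
            label = "UP" if sign > 0 else "DN"
            for attempt in range(max_retries):
                seed_de = rng.choice(pool, size=n_de_members, replace=False)
                seed_fill = rng.choice(non_de, size=n_fill, replace=False)
                variants = [frozenset(seed_de) | frozenset(seed_fill)]
                used = set(seed_de) | set(seed_fill)
                for _ in range(gsize - 1):
                    drop = rng.choice(sorted(seed_fill), size=r_swap, replace=False)
                    fresh_pool = [g for g in non_de if g not in used]
                    fresh = rng.choice(fresh_pool, size=r_swap, replace=False)
                    used.update(fresh)
                    members = (variants[0] - frozenset(drop)) | frozenset(fresh)
                    variants.append(members)
                if _pairwise_jaccard_ok(variants, intra_overlap, at_least=True):
                    break
            else:
                raise ValueError(
                    "could not satisfy intra-group overlap constraints"
                )
            names = []
            for mi, members in enumerate(variants, start=1):
                name = f"ENRICHED_{label}_GROUP{gi + 1}_SET{mi}"
                sets.append(
                    GeneSet(
                        name=name,
                        description=f"planted enriched ({label.lower()}-regulated)",
                        members=members,
                    )
                )
                enriched[name] = sign
                names.append(name)
            groups_out.append(tuple(names))
        group_members = [
            [s.members for s in sets if s.name in g] for g in groups_out
        ]
        for (i, a), (j, b) in combinations(enumerate(group_members), 2):
            for ma in a:
                for mb in b:
                    if len(ma & mb) / len(ma | mb) >= 0.5:
                        raise ValueError(
                            "inter-group overlap constraint violated"
                        )

    for di in range(1, n_decoy + 1):
        size = int(rng.integers(lo, hi + 1))
        if size > len(non_de):
            raise ValueError("decoy size exceeds number of non-DE genes")
        members = frozenset(rng.choice(non_de, size=size, replace=False))
        sets.append(
            GeneSet(name=f"DECOY_{di:04d}", description="decoy", members=members)
        )

    db = GeneSetDatabase(sets, source=f"synthetic(seed={seed})")
    new_truth = replace(
        truth,
        enriched_sets=dict(enriched),
        planted_clusters=tuple(groups_out),
    )
    return db, new_truth


def write_fixtures(
    matrix: ExpressionMatrix,
    db: GeneSetDatabase,
    truth: SimulationTruth,
    directory: str | Path,
) -> Path:
    """Write counts.tsv, classes.tsv, gene_sets.gmt and truth.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    io_formats.write_expression(matrix, directory / "counts.tsv")
    if matrix.classes is not None:
        with (directory / "classes.tsv").open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("sample\tclass\n")
            for s in matrix.samples:
                fh.write(f"{s}\t{matrix.classes[s]}\n")
    io_formats.write_gmt(db, directory / "gene_sets.gmt")
    truth.to_json(directory / "truth.json")
    return directory
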