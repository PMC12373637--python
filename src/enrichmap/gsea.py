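"""Preranked gene-set enrichment analysis.

The enrichment score (ES) is the maximal deviation from zero of the
classic weighted running sum over the ranked gene list: in-set genes
("hits") increment the sum by ``|score|**weight`` normalized by the
total hit weight, out-of-set genes decrement it by ``1/(N - n_set)``.
Significance comes from a gene-sampling permutation null: random sets
of the same size drawn from the ranked universe.  The normalized
enrichment score (NES) divides the ES by the mean magnitude of
same-sign null values, and the nominal p-value uses the add-one
permutation estimator.  Because a q-value filter far below the
permutation resolution is applied downstream, the far tail of the null
can optionally be extrapolated with a generalized Pareto fit to the
largest null values (the standard tail-approximation approach for
permutation p-values); the empirical estimator is always an upper
bound on the reported p.  Benjamini-Hochberg adjustment across all
tested sets yields the q-values.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .datatypes import EnrichmentResult, GeneSet, GeneSetDatabase, RankedList

__all__ = [
    "GseaParams",
    "restrict_sets",
    "enrichment_score",
    "permutation_null",
    "normalize_and_test",
    "bh_adjust",
    "run_gsea",
]

#: Minimum same-sign null values required before tail extrapolation.
_TAIL_MIN_NULL = 100
#: Extrapolate only when fewer than this many nulls reach the observed ES.
_TAIL_MAX_EXCEEDANCES = 10
#: Number of top null values used for the generalized Pareto tail fit.
_TAIL_FIT_SIZE = 250
#: Floor for extrapolated p-values.
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class GseaParams:
    """Tuning parameters of the preranked GSEA stage."""

    min_set_size: int = 15
    max_set_size: int = 500
    weight_exponent: float = 1.0
    n_permutations: int = 1000
    seed: int = 0
    extrapolate_tail: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.min_set_size <= self.max_set_size):
            raise ValueError("require 1 <= min_set_size <= max_set_size")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be at least 100")
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be non-negative")


def restrict_sets(
    db: GeneSetDatabase, ranks: RankedList, params: GseaParams = GseaParams()
) -> GeneSetDatabase:
    """Intersect every set with the ranked universe and apply size bounds.

    Sets whose intersected size falls outside
    ``[min_set_size, max_set_size]`` (or covers the whole universe) are
    dropped; database order is retained.
    """
    universe = set(ranks.genes)
    kept: list[GeneSet] = []
    for s in db:
        members = frozenset(m for m in s.members if m in universe)
        if params.min_set_size <= len(members) <= params.max_set_size and len(
            members
        ) < len(universe):
            kept.append(GeneSet(name=s.name, description=s.description, members=members))
    if not kept:
        raise ValueError(
            "no gene sets remain after restriction to the ranked universe; "
            "consider relaxing min_set_size/max_set_size"
        )
    return GeneSetDatabase(kept, source=db.source)


def _hit_weights(scores: np.ndarray, weight_exponent: float) -> np.ndarray:
    if weight_exponent == 0:
        return np.ones_like(scores)
    return np.abs(scores) ** weight_exponent


def enrichment_score(
    ranks: RankedList,
    set_members: Iterable[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray, tuple[str, ...]]:
    """Weighted Kolmogorov-Smirnov-like running-sum enrichment score.

    Returns ``(es, running_sum, leading_edge)`` where ``running_sum``
    holds the sum after each position of the ranked list.  The ES is
    the running-sum value of maximal absolute deviation from zero (the
    positive branch wins exact-magnitude ties).  The leading edge
    contains the in-set genes at or before the extremum for positive
    ES, and after it for negative ES, ordered by rank.
    """
    members = set(set_members)
    n_total = len(ranks)
    hit = np.fromiter(
        (g in members for g in ranks.genes), dtype=bool, count=n_total
    )
    k = int(hit.sum())
    if k == 0:
        raise ValueError("gene set does not intersect the ranked universe")
    if k == n_total:
        raise ValueError("gene set covers the entire ranked universe")
    w = np.where(hit, _hit_weights(ranks.scores, weight_exponent), 0.0)
    nr = w.sum()
    if nr <= 0:
        # All in-set scores are zero: fall back to uniform hit increments.
        w = hit.astype(float)
        nr = float(k)
    steps = np.where(hit, w / nr, -1.0 / (n_total - k))
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    pos_es = float(running[i_max])
    neg_es = float(running[i_min])
    if abs(pos_es) >= abs(neg_es):
        es = pos_es
        leading = tuple(
            g for i, g in enumerate(ranks.genes) if hit[i] and i <= i_max
        )
    else:
        es = neg_es
        leading = tuple(
            g for i, g in enumerate(ranks.genes) if hit[i] and i > i_min
        )
    return es, running, leading


def _sample_position_prefixes(
    n_universe: int,
    k_max: int,
    n_perm: int,
    rng: np.random.Generator,
    chunk_rows: int = 4096,
) -> np.ndarray:
    """Uniform without-replacement samples of size ``k_max`` from the universe.

    Each row is the prefix of an independent uniform permutation
    (partial Fisher-Yates), so the first ``k`` columns of a row are a
    uniform ``k``-subset for every ``k <= k_max``.
    """
    out = np.empty((n_perm, k_max), dtype=np.int32)
    done = 0
    base = np.arange(n_universe, dtype=np.int32)
    while done < n_perm:
        rows = min(chunk_rows, n_perm - done)
        arr = np.tile(base, (rows, 1))
        ridx = np.arange(rows)
        for j in range(k_max):
            r = rng.integers(j, n_universe, size=rows)
            vals = arr[ridx, r]
            arr[ridx, r] = arr[:, j]
            arr[:, j] = vals
        out[done : done + rows] = arr[:, :k_max]
        done += rows
    return out


def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, n_universe: int
) -> np.ndarray:
    """Vectorized ES for many hit-position sets at once.

    ``positions`` is (R, k), row-sorted ascending, 0-based.  The running
    sum attains its extrema immediately after a hit (peaks) or
    immediately before one (valleys); evaluating only those candidates
    reproduces the full scan exactly.
    """
    r, k = positions.shape
    w = weights[positions]
    nr = w.sum(axis=1, keepdims=True)
    degenerate = nr <= 0
    if degenerate.any():
        w = np.where(degenerate, 1.0, w)
        nr = np.where(degenerate, float(k), nr)
    cw = np.cumsum(w, axis=1) / nr
    miss = 1.0 / (n_universe - k)
    j = np.arange(1, k + 1)
    peaks = cw - (positions + 1 - j) * miss
    valleys = (cw - w / nr) - (positions - j + 1) * miss
    pos_es = peaks.max(axis=1)
    neg_es = valleys.min(axis=1)
    return np.where(np.abs(pos_es) >= np.abs(neg_es), pos_es, neg_es)


def permutation_null(
    ranks: RankedList, set_size: int, params: GseaParams = GseaParams()
) -> np.ndarray:
    """Null ES sample for random same-size gene sets (seeded, reproducible)."""
    n_universe = len(ranks)
    if not (1 <= set_size < n_universe):
        raise ValueError("set_size must be in [1, universe size)")
    rng = np.random.default_rng(params.seed)
    prefixes = _sample_position_prefixes(
        n_universe, set_size, params.n_permutations, rng
    )
    weights = _hit_weights(ranks.scores, params.weight_exponent)
    positions = np.sort(prefixes, axis=1)
    return _es_from_positions(positions, weights, n_universe)


def _gpd_tail_p(null_abs: np.ndarray, x: float) -> float | None:
    """Generalized Pareto estimate of the exceedance probability P(|null| >= x).

    Fits the top ``_TAIL_FIT_SIZE`` null magnitudes above a threshold
    midway between the last included and first excluded order statistic.
    Returns None when there is too little tail data or the fit fails.
    """
    n = null_abs.size
    n_exc = min(_TAIL_FIT_SIZE, n // 4)
    if n_exc < 30:
        return None
    top = np.sort(null_abs)[::-1]
    threshold = 0.5 * (top[n_exc - 1] + top[n_exc])
    exceed = top[:n_exc] - threshold
    exceed = exceed[exceed > 0]
    if exceed.size < 30 or x <= threshold:
        return None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shape, _, scale = stats.genpareto.fit(exceed, floc=0.0)
            tail = float(stats.genpareto.sf(x - threshold, shape, loc=0.0, scale=scale))
    except Exception:
        return None
    if not np.isfinite(tail):
        return None
    return exceed.size / n * tail


def normalize_and_test(
    es: float,
    null: Sequence[float] | np.ndarray,
    extrapolate_tail: bool = False,
) -> tuple[float, float, tuple[str, ...]]:
    """NES and nominal p-value of an observed ES against a null sample.

    NES = es / mean(|same-sign null values|); p uses the add-one
    estimator over same-sign null values.  ``es == 0`` maps to
    ``(0, 1)`` by convention; with no same-sign null values the result
    is flagged and ``p = 1``.  With ``extrapolate_tail`` the far tail
    (fewer than 10 exceedances) is refined by a generalized Pareto fit;
    the empirical estimate remains an upper bound.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null sample is empty")
    if es == 0:
        return 0.0, 1.0, ()
    same = null[null > 0] if es > 0 else null[null < 0]
    if same.size == 0:
        return 0.0, 1.0, ("no_same_sign_null",)
    mags = np.abs(same)
    nes = float(es / mags.mean())
    n_ge = int((mags >= abs(es)).sum())
    p = (1 + n_ge) / (1 + mags.size)
    flags: tuple[str, ...] = ()
    if (
        extrapolate_tail
        and n_ge < _TAIL_MAX_EXCEEDANCES
        and mags.size >= _TAIL_MIN_NULL
    ):
        p_tail = _gpd_tail_p(mags, abs(es))
        if p_tail is not None:
            p = min(p, max(p_tail, _P_FLOOR))
            flags = ("tail_extrapolated",)
    return nes, float(p), flags


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return stats.false_discovery_control(p, method="bh")


def run_gsea(
    ranks: RankedList,
    db: GeneSetDatabase,
    params: GseaParams = GseaParams(),
) -> list[EnrichmentResult]:
    """Full preranked GSEA over a gene-set database.

    Pipeline: restrict sets to the ranked universe, compute per-set ES
    and leading edge, build size-stratified permutation nulls (shared
    across sets of equal size), derive NES and nominal p per set, and
    BH-adjust across all tested sets.  Results are sorted by q-value,
    then |NES| descending, then name.  Fully reproducible given
    ``params.seed``; the null for a given set size does not depend on
    database order.
    """
    restricted = restrict_sets(db, ranks, params)
    n_universe = len(ranks)
    weights = _hit_weights(ranks.scores, params.weight_exponent)

    sizes = sorted({len(s.members) for s in restricted})
    rng = np.random.default_rng(params.seed)
    prefixes = _sample_position_prefixes(
        n_universe, max(sizes), params.n_permutations, rng
    )
    null_cache: dict[int, np.ndarray] = {}
    for k in sizes:
        positions = np.sort(prefixes[:, :k], axis=1)
        null_cache[k] = _es_from_positions(positions, weights, n_universe)
    del prefixes

    records: list[tuple[GeneSet, float, tuple[str, ...], float, float, tuple[str, ...]]] = []
    for s in restricted:
        es, _, leading = enrichment_score(ranks, s.members, params.weight_exponent)
        nes, p, flags = normalize_and_test(
            es, null_cache[len(s.members)], extrapolate_tail=params.extrapolate_tail
        )
        records.append((s, es, leading, nes, p, flags))

    qvals = bh_adjust([rec[4] for rec in records])
    results = [
        EnrichmentResult(
            set_name=s.name,
            size=len(s.members),
            es=es,
            nes=nes,
            p_value=p,
            q_value=float(q),
            leading_edge=leading,
            flags=flags,
        )
        for (s, es, leading, nes, p, flags), q in zip(records, qvals)
    ]
    results.sort(key=lambda r: (r.q_value, -abs(r.nes), r.set_name))
    return results
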