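"""Count preprocessing for the two-class RNA-Seq entry point.

The stages mirror the standard bulk RNA-Seq protocol: low-count genes are
removed with the published ``filterByExpr`` rule, between-sample scaling
factors come from the trimmed mean of M-values (TMM), a single common
negative-binomial dispersion is estimated by conditional maximum
likelihood, each gene gets a two-sided exact NB test, and genes are
scored as ``sign(log2FC) * -log10(p)`` for preranked enrichment.

The design is deliberately restricted to two classes with at least two
samples each and no covariates; experiments with one sample per class
must enter the pipeline through a pre-ranked RNK file instead.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import rankdata

from .datatypes import ExpressionMatrix, RankedList

__all__ = [
    "FilterConfig",
    "TMMFactors",
    "filter_low_counts",
    "tmm_factors",
    "cpm",
    "estimate_common_dispersion",
    "differential_test",
    "compute_ranks",
]

#: Floor applied to p-values before -log10 so rank scores stay finite.
P_FLOOR = 1e-300

#: Per-sample prior count used when computing log fold changes.
LFC_PRIOR_COUNT = 0.5

#: Bounded search interval for the common NB dispersion.
DISPERSION_BOUNDS = (1e-6, 4.0)


@dataclass(frozen=True)
class FilterConfig:
    """Constants of the low-count filter (published edgeR defaults)."""

    min_count: float = 10.0
    min_total_count: float = 15.0
    large_n: int = 10
    min_prop: float = 0.7

    def __post_init__(self) -> None:
        if self.min_count < 0 or self.min_total_count < 0 or self.large_n < 0:
            raise ValueError("filter constants must be non-negative")
        if not (0 < self.min_prop <= 1):
            raise ValueError("min_prop must be in (0, 1]")


@dataclass(frozen=True)
class TMMFactors:
    """Per-sample TMM scaling factors with geometric mean one."""

    factors: pd.Series
    reference_sample: str

    def __post_init__(self) -> None:
        values = self.factors.to_numpy(dtype=float)
        if (values <= 0).any():
            raise ValueError("TMM factors must be positive")
        log_gm = float(np.mean(np.log(values)))
        if abs(log_gm) > 1e-12:
            raise ValueError("TMM factors must have geometric mean 1")


def _require_two_classes(x: ExpressionMatrix, min_per_class: int = 1) -> tuple[str, str]:
    if x.classes is None:
        raise ValueError("class assignment not set on expression matrix")
    a, b = x.class_labels
    for label in (a, b):
        n = len(x.class_samples(label))
        if n < min_per_class:
            raise ValueError(
                f"class {label!r} has {n} sample(s); at least {min_per_class} "
                "required — use a pre-ranked RNK input for designs without "
                "replicates"
            )
    return a, b


def filter_low_counts(x: ExpressionMatrix, cfg: FilterConfig = FilterConfig()) -> ExpressionMatrix:
    """Remove genes too weakly expressed to test, keeping row order.

    Implements the published rule: a gene is kept iff it reaches the
    CPM cutoff ``min_count / median(library size) * 1e6`` in at least
    ``min(group sizes)`` samples (damped toward ``large_n * min_prop``
    when the smallest group is larger than ``large_n``) and its total
    count is at least ``min_total_count``.  Comparisons use a 1e-14
    tolerance so borderline genes are kept, matching the reference rule.
    """
    _require_two_classes(x)
    counts = x.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = x.samples[int(np.argmin(lib))]
        raise ValueError(f"sample {bad!r} has zero library size")
    a, b = x.class_labels
    n_small = min(len(x.class_samples(a)), len(x.class_samples(b)))
    min_n = float(n_small)
    if min_n > cfg.large_n:
        min_n = cfg.large_n + (min_n - cfg.large_n) * cfg.min_prop
    median_lib = float(np.median(lib))
    cpm_cutoff = cfg.min_count / median_lib * 1e6
    tol = 1e-14
    cpm_mat = counts / lib * 1e6
    keep_cpm = (cpm_mat >= cpm_cutoff).sum(axis=1) >= min_n - tol
    keep_total = counts.sum(axis=1) >= cfg.min_total_count - tol
    keep = keep_cpm & keep_total
    if not keep.any():
        raise ValueError("no genes pass the low-count filter")
    return ExpressionMatrix(x.counts.loc[keep], x.classes)


def tmm_factors(x: ExpressionMatrix) -> TMMFactors:
    """Trimmed mean of M-values scaling factors.

    The reference sample is the column whose upper quartile of nonzero
    CPM is closest to the mean upper quartile.  For every sample, log
    ratios M and average abundances A are computed over genes expressed
    in both the sample and the reference, doubly trimmed (30% of M, 5%
    of A, two-sided), and combined by a precision-weighted mean with
    inverse asymptotic binomial variances as weights.  Factors are
    rescaled to geometric mean one.
    """
    counts = x.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = x.samples[int(np.argmin(lib))]
        raise ValueError(f"sample {bad!r} has zero library size")
    cpm_mat = counts / lib * 1e6
    uq = np.array(
        [
            np.percentile(col[col > 0], 75) if (col > 0).any() else 0.0
            for col in cpm_mat.T
        ]
    )
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = counts[:, ref_idx]
    ref_lib = lib[ref_idx]
    log_factors = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        obs = counts[:, j]
        mask = (obs > 0) & (ref > 0)
        if not mask.any():
            continue
        p_obs = obs[mask] / lib[j]
        p_ref = ref[mask] / ref_lib
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        n = m.size
        lo_m = math.floor(n * 0.3) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * 0.05) + 1
        hi_a = n + 1 - lo_a
        rm = rankdata(m)
        ra = rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any():
            continue
        w = (lib[j] - obs[mask]) / (lib[j] * obs[mask]) + (
            ref_lib - ref[mask]
        ) / (ref_lib * ref[mask])
        wk = w[keep]
        if wk.sum() <= 0:
            continue
        f = float(np.sum(wk * m[keep]) / np.sum(wk))
        if np.isfinite(f):
            log_factors[j] = f
    log_factors -= log_factors.mean()
    factors = pd.Series(2.0 ** log_factors, index=list(x.samples))
    return TMMFactors(factors=factors, reference_sample=x.samples[ref_idx])


def cpm(
    x: ExpressionMatrix,
    f: TMMFactors | None = None,
    log: bool = False,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Counts per million over effective (TMM-scaled) library sizes.

    The log variant uses log2 with the prior count scaled to each
    sample's effective library size, so 2**logCPM converges to the
    linear CPM as ``prior_count -> 0``.
    """
    counts = x.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if f is not None:
        if tuple(f.factors.index) != x.samples:
            raise ValueError("TMM factors do not align with samples")
        lib = lib * f.factors.to_numpy(dtype=float)
    if not log:
        values = counts / lib * 1e6
    else:
        pc = prior_count * lib / lib.mean()
        values = np.log2((counts + pc) / (lib + 2 * pc) * 1e6)
    return pd.DataFrame(values, index=list(x.genes), columns=list(x.samples))


def _effective_lib_sizes(x: ExpressionMatrix, f: TMMFactors | None) -> np.ndarray:
    lib = x.counts.to_numpy(dtype=float).sum(axis=0)
    if f is not None:
        lib = lib * f.factors.to_numpy(dtype=float)
    return lib


def _class_columns(x: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    a, b = x.class_labels
    samples = list(x.samples)
    idx_a = np.array([samples.index(s) for s in x.class_samples(a)])
    idx_b = np.array([samples.index(s) for s in x.class_samples(b)])
    return idx_a, idx_b


def estimate_common_dispersion(
    x: ExpressionMatrix, factors: TMMFactors | None = None
) -> float:
    """Common NB dispersion by pooled conditional maximum likelihood.

    Counts are first rescaled to a common effective library size
    (geometric mean of the TMM-scaled totals); within each class the
    conditional likelihood given the gene's class total is then free of
    the gene's mean, and a single dispersion maximizing the sum over
    genes and classes is found by bounded search on [1e-6, 4].
    """
    _require_two_classes(x, min_per_class=2)
    if factors is None:
        factors = tmm_factors(x)
    counts = x.counts.to_numpy(dtype=float)
    lib = _effective_lib_sizes(x, factors)
    common = float(np.exp(np.mean(np.log(lib))))
    pseudo = counts * (common / lib)
    idx_a, idx_b = _class_columns(x)

    groups = [pseudo[:, idx_a], pseudo[:, idx_b]]

    def neg_cond_loglik(phi: float) -> float:
        r = 1.0 / phi
        total = 0.0
        for y in groups:
            n = y.shape[1]
            z = y.sum(axis=1)
            total += float(
                gammaln(y + r).sum()
                - y.shape[0] * n * gammaln(r)
                + gammaln(n * r) * y.shape[0]
                - gammaln(z + n * r).sum()
            )
        return -total

    res = minimize_scalar(
        neg_cond_loglik,
        bounds=DISPERSION_BOUNDS,
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(np.clip(res.x, *DISPERSION_BOUNDS))


def _exact_nb_pvalue(a: int, b: int, n_a: int, n_b: int, dispersion: float) -> float:
    """Two-sided exact NB test conditional on the total ``a + b``.

    ``a`` and ``b`` are the class total counts (after library-size
    equalization).  Under the null the class-A total given ``z = a + b``
    follows the NB analogue of the hypergeometric distribution with
    shape parameters ``n_a / dispersion`` and ``n_b / dispersion``; the
    p-value doubles the smaller tail (observed value included) and is
    capped at 1.  ``dispersion == 0`` reduces to the conditional
    binomial (Poisson) test.
    """
    z = a + b
    if z == 0:
        return 1.0
    # canonical orientation makes the test exactly label-symmetric
    if (a, n_a) > (b, n_b):
        a, b, n_a, n_b = b, a, n_b, n_a
    k = np.arange(z + 1)
    if dispersion < 1e-10:
        # Poisson limit: binomial conditional distribution.
        logp = (
            gammaln(z + 1)
            - gammaln(k + 1)
            - gammaln(z - k + 1)
            + k * math.log(n_a / (n_a + n_b))
            + (z - k) * math.log(n_b / (n_a + n_b))
        )
    else:
        r_a = n_a / dispersion
        r_b = n_b / dispersion
        logp = (
            gammaln(k + r_a)
            - gammaln(k + 1)
            + gammaln(z - k + r_b)
            - gammaln(z - k + 1)
        )
    logp = logp - logsumexp(logp)
    p = np.exp(logp)
    lower = float(p[: a + 1].sum())
    upper = float(p[a:].sum())
    return min(1.0, 2.0 * min(lower, upper))


def differential_test(
    x: ExpressionMatrix,
    dispersion: float,
    factors: TMMFactors | None = None,
) -> pd.DataFrame:
    """Per-gene two-sided exact NB test between the two classes.

    Returns a DataFrame indexed by gene with columns
    ``log2_fold_change`` (class B vs class A, computed from class-mean
    CPMs with a 0.5 per-sample prior count), ``p_value``, ``adjusted_p``
    (Benjamini-Hochberg over all tested genes), and ``mean_cpm``.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    _require_two_classes(x, min_per_class=2)
    if factors is None:
        factors = tmm_factors(x)
    counts = x.counts.to_numpy(dtype=float)
    lib = _effective_lib_sizes(x, factors)
    common = float(np.exp(np.mean(np.log(lib))))
    pseudo = counts * (common / lib)
    idx_a, idx_b = _class_columns(x)
    n_a, n_b = len(idx_a), len(idx_b)

    sum_a = np.rint(pseudo[:, idx_a].sum(axis=1)).astype(np.int64)
    sum_b = np.rint(pseudo[:, idx_b].sum(axis=1)).astype(np.int64)
    pvals = np.array(
        [
            _exact_nb_pvalue(int(a), int(b), n_a, n_b, dispersion)
            for a, b in zip(sum_a, sum_b)
        ]
    )

    # log2 fold change from prior-damped class mean CPMs.
    prior = LFC_PRIOR_COUNT
    cpm_a = (counts[:, idx_a].sum(axis=1) + prior * n_a) / (
        lib[idx_a].sum() + n_a
    ) * 1e6
    cpm_b = (counts[:, idx_b].sum(axis=1) + prior * n_b) / (
        lib[idx_b].sum() + n_b
    ) * 1e6
    lfc = np.log2(cpm_b) - np.log2(cpm_a)  # difference form: label swap negates exactly

    mean_cpm = (counts / lib * 1e6).mean(axis=1)

    from .gsea import bh_adjust  # local import avoids a module cycle

    padj = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "p_value": pvals,
            "adjusted_p": padj,
            "mean_cpm": mean_cpm,
        },
        index=list(x.genes),
    )


def compute_ranks(de: pd.DataFrame) -> RankedList:
    """Signed significance score per gene: ``sign(log2FC) * -log10(p)``.

    P-values are floored at 1e-300 before the log; a zero fold change
    yields score 0.  The resulting list is ordered by descending score
    with lexicographic tie-breaking.
    """
    if len(de) == 0:
        raise ValueError("differential expression table is empty")
    p = np.maximum(de["p_value"].to_numpy(dtype=float), P_FLOOR)
    sign = np.sign(de["log2_fold_change"].to_numpy(dtype=float))
    scores = sign * (-np.log10(p))
    # -0.0 would survive sign() * 0; normalize to +0.0 for determinism
    scores = scores + 0.0
    return RankedList(zip(de.index, scores))
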