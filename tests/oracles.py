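"""Independent reference implementations used only as test oracles.

Deliberately written as literal, scalar transcriptions of the published
definitions (plain Python loops, no code shared with the package) so
they can serve as independent cross-checks.
"""
from __future__ import annotations

import math


def brute_force_es(genes, scores, members, weight_exponent=1.0):
    """Literal running-sum enrichment score.

    Walk the ranked list; hits add |score|**w / (sum of in-set
    |score|**w), misses subtract 1/(N - n_set); return the running-sum
    value of maximal absolute deviation (positive branch wins ties).
    """
    n = len(genes)
    hits = [g in members for g in genes]
    n_hit = sum(hits)
    assert 0 < n_hit < n
    denom = 0.0
    for g, s, h in zip(genes, scores, hits):
        if h:
            denom += abs(s) ** weight_exponent
    run = 0.0
    best_pos = -math.inf
    best_neg = math.inf
    seq = []
    for g, s, h in zip(genes, scores, hits):
        if h:
            if denom > 0:
                run += (abs(s) ** weight_exponent) / denom
            else:
                run += 1.0 / n_hit
        else:
            run -= 1.0 / (n - n_hit)
        seq.append(run)
        best_pos = max(best_pos, run)
        best_neg = min(best_neg, run)
    if abs(best_pos) >= abs(best_neg):
        return best_pos, seq
    return best_neg, seq


def filter_by_expr_oracle(
    counts,
    groups,
    min_count=10.0,
    min_total_count=15.0,
    large_n=10,
    min_prop=0.7,
):
    """Line-by-line transcription of the published low-count filter rule.

    counts: list of per-gene lists; groups: per-sample class labels.
    Returns a keep/drop boolean per gene.
    """
    n_genes = len(counts)
    n_samples = len(groups)
    lib = [sum(counts[g][j] for g in range(n_genes)) for j in range(n_samples)]
    sizes = {}
    for lab in groups:
        sizes[lab] = sizes.get(lab, 0) + 1
    min_n = float(min(sizes.values()))
    if min_n > large_n:
        min_n = large_n + (min_n - large_n) * min_prop
    sorted_lib = sorted(lib)
    m = len(sorted_lib)
    if m % 2 == 1:
        median_lib = sorted_lib[m // 2]
    else:
        median_lib = 0.5 * (sorted_lib[m // 2 - 1] + sorted_lib[m // 2])
    cutoff = min_count / median_lib * 1e6
    tol = 1e-14
    keep = []
    for g in range(n_genes):
        n_pass = 0
        for j in range(n_samples):
            if counts[g][j] / lib[j] * 1e6 >= cutoff:
                n_pass += 1
        total = sum(counts[g])
        keep.append(n_pass >= min_n - tol and total >= min_total_count - tol)
    return keep


def _average_ranks(values):
    """1-based average ranks (ties averaged), scalar implementation."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def tmm_oracle(counts):
    """Step-by-step transcription of the trimmed mean of M-values.

    counts: per-gene lists (genes x samples).  Reference = sample whose
    75th percentile of nonzero CPM is closest to the mean such
    percentile; per sample, M/A over genes positive in both, doubly
    trimmed (30% of M, 5% of A, two-sided by rank), combined with
    inverse binomial-variance weights; factors normalized to geometric
    mean one.
    """
    n_genes = len(counts)
    n_samples = len(counts[0])
    lib = [sum(counts[g][j] for g in range(n_genes)) for j in range(n_samples)]

    def upper_quartile(j):
        vals = sorted(
            counts[g][j] / lib[j] * 1e6 for g in range(n_genes) if counts[g][j] > 0
        )
        if not vals:
            return 0.0
        # linear interpolation, matching the common percentile definition
        pos = 0.75 * (len(vals) - 1)
        lo = int(math.floor(pos))
        hi = int(math.ceil(pos))
        if lo == hi:
            return vals[lo]
        return vals[lo] + (pos - lo) * (vals[hi] - vals[lo])

    uq = [upper_quartile(j) for j in range(n_samples)]
    mean_uq = sum(uq) / len(uq)
    ref = min(range(n_samples), key=lambda j: (abs(uq[j] - mean_uq), j))

    log_factors = []
    for j in range(n_samples):
        m_vals, a_vals, w_vals = [], [], []
        for g in range(n_genes):
            yo, yr = counts[g][j], counts[g][ref]
            if yo > 0 and yr > 0:
                po, pr = yo / lib[j], yr / lib[ref]
                m_vals.append(math.log2(po / pr))
                a_vals.append(0.5 * math.log2(po * pr))
                w_vals.append(
                    (lib[j] - yo) / (lib[j] * yo) + (lib[ref] - yr) / (lib[ref] * yr)
                )
        if not m_vals:
            log_factors.append(0.0)
            continue
        n = len(m_vals)
        lo_m = math.floor(n * 0.3) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * 0.05) + 1
        hi_a = n + 1 - lo_a
        rm = _average_ranks(m_vals)
        ra = _average_ranks(a_vals)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
                num += w_vals[i] * m_vals[i]
                den += w_vals[i]
        log_factors.append(num / den if den > 0 else 0.0)
    mean_lf = sum(log_factors) / len(log_factors)
    return [2.0 ** (f - mean_lf) for f in log_factors], ref


def exact_nb_conditional_p(a, b, n_a, n_b, dispersion):
    """Direct summation of the conditional NB tail probabilities.

    Conditional distribution of the class-A total given z = a + b with
    per-class shape n/dispersion; p doubles the smaller tail (observed
    value included), capped at 1.
    """
    z = a + b
    r_a = n_a / dispersion
    r_b = n_b / dispersion
    logw = [
        math.lgamma(k + r_a)
        - math.lgamma(k + 1)
        + math.lgamma(z - k + r_b)
        - math.lgamma(z - k + 1)
        for k in range(z + 1)
    ]
    mx = max(logw)
    w = [math.exp(v - mx) for v in logw]
    total = sum(w)
    lower = sum(w[: a + 1]) / total
    upper = sum(w[a:]) / total
    return min(1.0, 2.0 * min(lower, upper))


class UnionFind:
    """Minimal union-find used as the clustering oracle."""

    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def components(self):
        groups = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return sorted(
            (frozenset(g) for g in groups.values()),
            key=lambda s: (-len(s), min(s)),
        )


def bh_oracle(pvals):
    """Hand step-up: q_(i) = min_{j>=i} p_(j) * m / j, input order kept."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = min(running, 1.0)
    return q
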