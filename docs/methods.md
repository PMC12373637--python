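# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the test suite demonstrates.

## Scope and assumptions

The pipeline targets the common two-class bulk RNA-Seq comparison (it also
suits single-cell pseudo-bulk counts): non-negative counts for one organism's
genes (HGNC symbols or Ensembl IDs), exactly two conditions, no covariates,
no batch structure. Batch correction and outlier removal are deliberately out
of scope; data needing them should enter through a pre-ranked RNK file.
Designs without replicates (one sample per class) are refused at the
differential-expression stage for the same reason — no dispersion is
estimable — and are likewise directed to the RNK entry point.

Gene identifiers are normalized once at parse time (symbols upper-cased,
Ensembl version suffixes stripped) so expression tables, RNK files and GMT
databases join reliably. Readers reject structural problems (duplicates,
negative counts, ragged rows, non-numeric scores) rather than repairing them.

## Count preprocessing

**Low-count filter.** The published *filterByExpr* rule, with the published
default constants `min_count = 10`, `min_total_count = 15`, `large_n = 10`,
`min_prop = 0.7`: keep gene *g* iff

* CPM_gj ≥ `min_count / median_j(N_j) × 1e6` in at least `n*` samples, where
  `n*` is the smaller group size, damped to `large_n + (n_small − large_n) ·
  min_prop` when the smaller group exceeds `large_n`; and
* `Σ_j y_gj ≥ min_total_count`,

both compared with a 1e-14 tolerance. The filter runs on raw library sizes,
before normalization. On dev fixtures the survivor set is identical to
Bioconductor edgeR's `filterByExpr`.

**TMM normalization.** The reference sample is the column whose 75th
percentile of nonzero CPM lies closest to the mean such percentile. For each
sample, over genes with positive counts in both sample and reference,

* `M_g = log2[(y_gj/N_j) / (y_gr/N_r)]`, `A_g = ½ log2[(y_gj/N_j)(y_gr/N_r)]`;
* genes in the central 40 % of the M-ranks **and** central 90 % of the A-ranks
  are retained (two-sided trims of 30 % and 5 %);
* the factor is `2^(Σ w_g M_g / Σ w_g)` with the inverse asymptotic binomial
  variances `w_g = (N_j − y_gj)/(N_j y_gj) + (N_r − y_gr)/(N_r y_gr)`;
* factors are rescaled so their geometric mean is exactly 1.

A degenerate sample (no shared positive genes, or empty trim window) falls
back to factor 1. Note that the precision weights are *not* scale-free, so
TMM is only approximately invariant (a few percent) to rescaling a single
column — a property shared by the reference implementation — while the
log-ratios themselves are exactly scale-free.

**Common dispersion.** Counts are rescaled to a common effective library size
(geometric mean of TMM-scaled totals), making the within-class conditional
likelihood given each gene's class total free of the gene mean:

`ℓ_g(α) = Σ_classes [ Σ_j lgamma(y'_gj + 1/α) + lgamma(n_c/α) − lgamma(z_gc + n_c/α) − n_c·lgamma(1/α) ]`

summed over genes and maximized by bounded scalar search on `α ∈ [1e-6, 4]`
(tolerance 1e-6) — bounds that bracket realistic bulk RNA-Seq dispersions.
The linear library rescaling is a deliberate simplification of the iterative
quantile adjustment used by the reference implementation; parameter-recovery
simulations (α = 0 → estimate at the lower bound; α = 0.2 → 0.200 at 2 000
genes) and the type-I error checks bound its effect.

**Exact test.** For each gene, with rescaled class sums *a*, *b* (rounded to
integers) and total *z = a + b*, the class-A sum under the null follows the
NB analogue of the hypergeometric distribution,

`P(A = k | z) ∝ Γ(k + n_A/α)/k! · Γ(z − k + n_B/α)/(z − k)!`,

and the two-sided p doubles the smaller tail (observed value included),
capped at 1. `α < 1e-10` switches to the conditional binomial (Poisson
limit). The computation is canonically oriented so that swapping class labels
preserves p-values bit-for-bit and exactly negates fold changes. Fold changes
are `log2` ratios of class-mean CPMs damped with a 0.5 per-sample prior
count; BH adjustment runs over all tested genes.

**Rank score.** `score = sign(log2FC) · (−log10 p)` with p floored at 1e-300
(keeping scores finite) and descending order, ties broken lexicographically —
a deterministic, monotone transform of significance.

## Preranked GSEA

The enrichment score is the classic weighted running sum: walking the ranked
list, in-set genes add `|score|^w / Σ_set |score|^w` (uniform increments if
that sum is zero), others subtract `1/(N − n_set)`; ES is the running-sum
value of maximal |deviation|, the positive branch winning exact ties. The
leading edge contains the in-set genes at or before the extremum (after it,
for negative ES). Default weight exponent 1; set-size bounds 15–500 after
intersection with the ranked universe (common preranked-GSEA practice,
exposed in configuration).

**Null model.** Gene-sampling permutations: `n_permutations` uniform
same-size subsets of the universe, sampled as prefixes of partial
Fisher–Yates permutations (vectorized, chunked; the ES of a sampled subset is
evaluated from its sorted hit positions only, which reproduces the full scan
exactly). Nulls are cached per set size and are independent of database
order; every random draw flows from the explicit seed — there is no global
random state.

**NES / p / q.** `NES = ES / mean |same-sign null|`; nominal
`p = (1 + #{same-sign null with |null| ≥ |ES|}) / (1 + #{same-sign null})`;
`ES = 0` maps to `(NES, p) = (0, 1)`; a missing same-sign null yields `p = 1`
with a warning flag. Q-values are Benjamini–Hochberg over all tested sets.

**Tail refinement.** The add-one estimator cannot report p below
`1/(n_same + 1)`, yet the downstream node filter keeps only `q ≤ 1e-4`; after
the BH multiplier (≈ m/rank) even 1e5 permutations cannot reach that bar.
When fewer than 10 of at least 100 same-sign null values reach the observed
ES, the exceedance probability is therefore refined by a generalized Pareto
fit to the largest 250 null magnitudes above a mid-order-statistic threshold
— the standard tail-approximation technique for permutation p-values. The
empirical add-one estimate always remains an upper bound on the reported p,
extrapolated values are floored at 1e-300, and the refinement can be disabled
(`extrapolate_tail=False`, CLI `--no-tail-extrapolation`); with it disabled
the CLI warns when the q-filter lies below the estimator's resolution.
Validity is checked empirically: on 500 random decoy sets the p distribution
remains stochastically above uniform.

## Enrichment map

Nodes are results with `q ≤ q_max` (default 1e-4, boundary inclusive); edges
connect pairs with Jaccard similarity ≥ `similarity_min` (default 0.5,
inclusive), computed on member sets restricted to the ranked universe so node
sizes and overlaps refer to the same gene space (a configuration switch
restores full-set similarity). Construction is deterministic: nodes and edges
in lexicographic order.

Clustering defaults to connected components of the thresholded graph — the
minimal reading of "groups of highly overlapping pathways" — with greedy
modularity communities (similarity-weighted) as an option for dense maps.
Cluster ids descend by size with lexicographic tie-breaks. Labels take the
top three words of member set names by frequency (ties alphabetical) after
tokenizing on non-alphanumerics, lowercasing, and dropping a fixed shipped
stop-word list (English function words, generic nomenclature words such as
"pathway"/"process"/"regulation", and database prefixes); singleton clusters
use their own name truncated to 60 characters. Hull geometry and layout are
out of scope — cluster membership is exported instead so any downstream tool
can draw the map.

## Synthetic data

`simulate_counts` draws per-gene relative abundances from a log-normal
(meanlog 4.5, sdlog 1.2 — median ≈ 60–90 counts per gene at the default
library sizes, a realistic bulk profile with a heavy right tail), library
sizes uniform in (1e6, 2e6), and counts NB with variance `μ + αμ²` (default
α = 0.1, typical for bulk data). A fraction (default 10 %) of genes receives
±log2FC (default 2) in class B with balanced signs; folds are applied without
renormalizing columns, planting exactly the composition bias TMM corrects.

`simulate_genesets` builds enriched sets of size 30 drawing ≥ 60 % of members
from same-sign DE genes, organized into overlap groups (default two groups,
alternating sign): group members perturb a common seed set by swapping
`r = ⌊size(1 − J*)/(2(1 + J*))⌋` filler members, which guarantees pairwise
Jaccard ≥ J* (default 0.6, safely above the 0.5 edge threshold); constraints
are verified post-hoc with bounded retries rather than solved exactly. Decoys
sample uniformly from non-DE genes with sizes uniform in (20, 60). Every
fixture is byte-reproducible from (parameters, seed).

What the generator does **not** emulate: gene length and GC effects,
single-cell zero inflation, tagwise dispersion, correlated gene modules
outside the planted sets, realistic pathway nomenclature. Passing the
end-to-end recovery tests therefore demonstrates that the pipeline's
machinery is correct and calibrated under its own model assumptions, not that
it is robust to every artefact of real libraries.

## Problem sizes used in the checks

The end-to-end recovery check runs the full default study (10 000 genes,
3 + 3, 205 sets, 1e5 permutations) over ten seeds; calibration checks use
2 000-gene null simulations; oracle equivalence uses 200 random instances
with universes up to 50 genes — sizes chosen as the smallest that make the
statistical assertions sharp (e.g. ±0.015 around the nominal type-I error).

## Known limitations

* One common dispersion for all genes; no tagwise/trended moderation. Genes
  whose true dispersion deviates strongly are mis-calibrated individually,
  though the pooled calibration holds.
* The linear library-size equalization before the exact test is approximate
  for strongly unequal libraries (the defaults span a 2× range).
* Generalized-Pareto extrapolated p-values are model-based beyond the
  permutation support; they are used only to order results far below the
  q-filter and are always bounded above by the empirical estimator.
* Jaccard is the only similarity metric (the overlap/combined variants common
  in desktop tools are not implemented; the parameter token leaves room).
* XLSX input is not supported in the core; convert to TSV/CSV first.
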