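# Methods

## The single-pair geneset statistic

The unit of analysis is one matched pair of expression profiles on a
common gene index, both on the log2 scale. For a geneset *S* the paired
differences d_g = case_g − control_g over the measured members of *S* are
tested with the Wilcoxon signed-rank test:

* zero differences are dropped (the classical signed-rank reduction); the
  number of nonzero differences n is reported alongside the set size;
* |d| is ranked with midranks; W⁺ and W⁻ are the rank sums of positive
  and negative differences, so W⁺ + W⁻ = n(n+1)/2 always;
* direction is "up" iff W⁺ > W⁻, "down" iff W⁺ < W⁻, "none" at equality;
* the two-sided p is 2·P(W ≤ min(W⁺, W⁻)) under the sign-flip null.

The statistic assumes only that, under the null, each gene's paired
difference is symmetric around zero — no distributional form, no variance
estimate, which is what makes it usable at n-of-1. It detects a
*coherent* location shift of the geneset; a set in which half the genes go
up and half down will (correctly, given the model) score near null.

### Null distribution: exact vs approximate

For n ≤ 25 (`exact_threshold`, configurable) the exact null of W⁺ is
computed by convolving the point masses {0, r_i} over the doubled
midranks. Doubling makes midranks integral, so this is exact for tied as
well as tie-free data and is identical to enumerating all 2ⁿ sign
assignments, at polynomial cost. For n > 25 a normal approximation is
used with (i) the tie-corrected variance n(n+1)(2n+1)/24 − Σ(t³−t)/48,
(ii) a 0.5 continuity correction toward the mean, and (iii) an Edgeworth
kurtosis term: the null of W⁺ is symmetric, so the leading departure from
normality is the fourth cumulant κ₄ = −Σ r_i⁴/8, and the correction
F(x) ≈ Φ(x) − φ(x)·(γ₂/24)(x³ − 3x) with γ₂ = κ₄/σ⁴ reduces the
worst-case absolute error against the exact null from ≈0.017 to ≈0.0014
at n = 10 and below 10⁻³ for all larger n. Degenerate genesets (fewer
than 2 nonzero differences) get p = 1 and are flagged rather than
erroring, so an all-zero geneset never aborts a scan.

### Multiple testing and Z-scores

Per pair, raw p-values are adjusted across all m tested genesets with
Benjamini–Hochberg (FDR) and Bonferroni (min(1, m·p)); both are reported
and the retention criteria `fdr_05`, `bonf_01`, `bonf_05` are inclusive
(a set exactly at the threshold is kept). The default retention rule is
Bonferroni ≤ 1%, which favours short, interpretable mechanism lists.
The signed Z is z = sign·Φ⁻¹(1 − p/2) computed by default from the
Bonferroni-adjusted p (configurable to FDR), with p clamped at 1e−300 so
Z stays finite; z = 0 when the direction is "none". Whether a one- or
two-sided transform is "right" is underdetermined — the two-sided form was
chosen because the retention p-values are two-sided, and the choice is a
visible `z_source` parameter in the output header.

## Cohort prioritization

With several pairs scored against the same geneset universe, each
mechanism is ranked by the number of pairs in which it reaches
Bonferroni ≤ α (default 1%); mechanisms significant in zero pairs are
dropped. Equal counts are ordered by |mean per-pair z| descending and
then by set id — the tie rule is a convention chosen for determinism and
for favouring the stronger shared signal; nothing downstream depends on
it beyond reproducibility. Non-significant pairs still contribute their
z to the per-pair matrix (useful for seeing sub-threshold agreement) but
not to the count.

## Preprocessing

* **Transcript collapse**: when several alternative transcripts map to one
  gene symbol, the row with the maximal mean expression across all samples
  in the table is kept; ties keep the first row in file order. The mean
  over all samples (rather than, say, per-sample maxima) keeps the choice
  symmetric in case and control.
* **log2**: linear inputs (e.g. RPKM) get log2(x + pseudocount), default
  pseudocount 1 to absorb zeros. No low-expression filter is applied
  anywhere — the rank statistic tolerates the resulting noisy
  low-abundance differences, and filtering would silently change each
  geneset's n.
* **Size filter**: genesets are restricted to their measured members and
  kept when that effective size is within [15, 500], inclusive. Counting
  *after* intersection with the measured universe is a deliberate choice:
  the statistic only ever sees measured genes, so the bound should apply
  to what is actually tested. Both bounds are parameters.
* Gene identifiers are matched as exact case-sensitive strings; identifier
  harmonization across platforms/species is the caller's responsibility.

## DEG baselines

Two conventional comparators are implemented. For a lone pair, genes are
called deregulated purely by fold change (|Δlog2| ≥ log2(fold), default
1.5-fold, inclusive) — at n = 1 nothing better exists. For replicated
groups, genes passing |mean difference| ≥ log2(fold) (default 2-fold) are
tested with a two-sample t-test — Welch by default, since a 4-vs-8 design
with possibly unequal variances is exactly where the pooled test is
fragile; pooled is available via `equal_var=True` — and BH-adjusted over
the *selected* genes only, mirroring the two-step filter-then-test order.
Retained genes split into up/down by the sign of the mean difference, and
each list is Fisher-enriched independently against every geneset on the
(DE, All) × (In set, Not in set) table. The enrichment test is one-sided
(greater) by default — the over-representation convention, identical to
the hypergeometric tail — with two-sided available. Odds ratios report
both the raw ad/bc (∞ when bc = 0 with ad > 0) and the Haldane–Anscombe
(+0.5 per cell) corrected value.

## Semantic similarity (ITS)

Term relatedness uses Jiang's information-theoretic measure. Annotations
are propagated up the DAG (a term inherits the genes of all descendants;
`is_a` and `part_of` are both hierarchical by default, with a flag to
restrict to `is_a`), the information content of a term is
IC(t) = −ln(|genes(t)|/|genes(root)|) normalized by the corpus maximum so
IC ∈ [0, 1] with IC(root) = 0, and

    ITS(a, b) = 1 − (IC(a) + IC(b) − 2·IC(MICA(a, b))) / 2

where MICA is the common ancestor with maximal IC. This normalization
guarantees the documented [0, 1] range with ITS = 1 exactly at a = b.
Terms with no propagated annotations are unscored (excluded) rather than
given infinite IC. ITS ≥ 0.7, inclusive, is the relatedness predicate
used by the evaluation utilities. The IC table is corpus-dependent:
similarities computed from different annotation snapshots are not
comparable to the third decimal, which is why the evaluation reports the
threshold rule rather than raw similarity distributions.

## Concordance evaluation

The overlap of two mechanism lists over a shared universe is tested on the
2×2 (shared, only-1) × (only-2, neither) with a one-sided Fisher p and
odds ratio. The "mathematical universe" is a parameter — the natural
choice, and the default expected by the helpers, is the size-filtered
geneset collection both methods could have reported; its value is recorded
in the output since the OR scales with it.

Precision–recall curves sweep cutoffs down a ranked list (p-values
ascending or sample counts descending; tied keys enter as one all-or-none
cutoff group so arbitrary within-tie order cannot tilt the curve).
Under ITS matching, a prediction is a true positive if it is related
(ITS ≥ 0.7) to *any* gold term; for recall each gold term is counted at
most once no matter how many predictions match it, keeping
precision and recall independently interpretable when the gold standard
contains clusters of related terms. KEGG-style identifiers have no IC and
are rejected for ITS matching with a clear error.

## Synthetic data

The generator emulates the two study shapes the pipeline targets — a
single case/control pair, and a cohort of pairs optionally backed by
replicate groups (default 4 case vs 8 control) — with planted ground
truth. Control expression is N(6, 2²) on the log2 scale; the case adds
paired noise N(0, 0.5²) and a coherent ±δ (default 1 log2 unit) to every
gene of a planted set. Defaults (5000 genes, 200 sets of 15–50 genes)
are sized so full simulation suites run in seconds. Options cover
disjoint genesets (required for clean type-I estimates, since overlapping
sets are dependent), partial planting (only a fraction of a set shifts),
heavy-tailed t(3) noise rescaled to the same sd, and shared-vs-private
planting across cohort pairs. Toy ontologies are balanced `is_a` trees
with optional diamond edges and leaf-only annotations, so internal-term
annotation arises purely from propagation.

What the generator does **not** emulate: count-level sampling noise and
its mean–variance relation, probe-level microarray artifacts, correlated
expression within real pathways beyond the planted shift, partial or
antagonistic deregulation patterns, and annotation incompleteness.
Passing the simulation suites therefore demonstrates the statistic's
calibration and power under its own model assumptions, not performance on
any particular real dataset.

## Verification problem sizes

The test suite and `scripts/acceptance.py` use: 500 random genesets
(n ≤ 12) against full 2ⁿ enumeration; 1000 genesets for the rank-sum and
antisymmetry identities; type-I error from 10 null studies × 1000 disjoint
genesets (sizes 15–50, pooled band 0.05 ± 3·SE); power from 100 seeded
studies with one planted set (δ = 1, σ = 0.5, 30 genes, Bonferroni over
200 sets, success = p_bonf ≤ 0.01 in ≥ 95%); cohort recovery from 20
seeded 3-pair cohorts (shared set must rank first with count 3 in ≥ 95%);
30 randomized 2×2 tables (universe ≤ 500) against direct hypergeometric
summation; and toy DAGs of ≤ 50 terms for the ITS axioms with brute-force
MICA. These sizes keep the full suite under a minute while leaving the
binomial uncertainty of every rate well inside its acceptance band.

## Known limitations

* Genesets sharing genes yield dependent p-values within a pair; the
  Bonferroni/BH adjustments treat them as a flat family.
* The statistic detects coherent shifts only; split up/down deregulation
  within one set cancels.
* Exact-null cost grows as n·Σr (doubled-rank convolution); the n ≤ 25
  default keeps per-geneset cost trivial, and the approximation beyond it
  is accurate to ~10⁻³.
* ITS values inherit every bias of the annotation corpus; the 0.7
  threshold is a convention validated elsewhere, not recalibrated here.
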