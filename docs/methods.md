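# Methods

This document describes the statistical methods implemented in
`mirenrich`, the synthetic data model used to validate them, and the
reproducibility contract of the sampler.

## Problem setting

Given a table of predicted miRNA→gene target interactions, a collection
of gene sets (annotation terms, e.g. GO categories or pathways) over a
gene universe, and an experimentally derived list of miRNAs, the task is
to decide which terms are over-represented among the predicted targets
of the list.

Notation: `N` genes in the universe, a term with `K` genes, an input
list whose union of predicted targets covers `n` universe genes, of
which `k` fall in the term.

## Standard hypergeometric test

`standard_enrichment` computes the classic one-sided
over-representation p-value

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

via `scipy.stats.hypergeom.sf(k - 1, N, K, n)`, which is identical to a
one-sided Fisher's exact test on the 2×2 table. Worked example: with
`k = 250, n = 10057, K = 327, N = 15733`, `p = 5.97e-7`.

This test assumes the `n` target genes are a uniform draw from the
universe. For miRNA target predictions that assumption fails: genes
with long 3'UTRs (or otherwise many predicted sites) are far more
likely to enter any target union, so terms composed of such genes look
enriched for *every* input list.

## Empirical resampling test

`empirical_enrichment` replaces the uniform-gene null with the actual
sampling distribution over miRNA lists: draw random same-size miRNA
sets (without replacement, uniformly from all miRNAs in the prediction
table), recompute the statistic for each draw, and report

    p = (number of draws with statistic >= observed) / (number of draws)

The inclusive `>=` with the "plain" rule gives an unbiased exceedance
estimate; the `add_one` rule `(x + 1)/(m + 1)` is available for a
guaranteed-valid (never zero) p-value. Proportion-valued statistics are
compared with a relative tie tolerance of 1e-12 so that
floating-point noise in equal ratios does not flip exceedance counts;
integer counts are compared exactly.

Three statistics are supported per term:

- `union_count` — number of universe genes in the term hit by the union
  of predicted targets (the `k` above).
- `union_proportion` — `union_count` divided by the union size `n`
  (self-normalising across draws with different union sizes).
- `multihit` — each gene scores the total number of predicted binding
  sites over the input miRNAs; the statistic is the term's share of the
  total score. Because the gene score is a sum over miRNAs, per-miRNA
  term scores are precomputed once and a draw's statistic is a single
  matrix lookup, making this statistic as cheap as the union ones.

Per-term null moments (mean, variance) are accumulated by streaming
Welford/chunk-merge updates; only exceedance counts and moments are
kept, never the raw null vectors, so memory is independent of the
iteration count. Benjamini–Hochberg adjustment
(`statsmodels.stats.multitest`, `fdr_bh`) produces q-values.

`exact_enumeration_enrichment` enumerates all `C(M, m)` subsets when
that number is at most 100 000 and returns exact p-values. It is the
oracle used by the test suite: sampled p-values must land within
3 Monte-Carlo standard errors of the enumerated ones.

### Performance

Union statistics use bit-packed boolean target rows (`numpy.packbits`
into `uint64` words): a draw's union is a `bitwise_or` reduction and
term overlaps are popcounts (`numpy.bitwise_count`) against packed term
masks. On the default synthetic scale (200 miRNAs × 3000 genes ×
100 terms) one million iterations run in about a minute on one core.

### Reproducibility contract

Sampling is counter-based: iteration batch `b` (fixed batch size 1024)
is generated from `numpy.random.Philox` keyed by `(seed, b)`. The
stream is therefore *prefix-stable*: the first `k` iterations of a run
are identical regardless of the total iteration count, results are
independent of chunking, and reruns with the same seed are
bit-identical — the test suite asserts byte-identical output files.
Subsets are drawn uniformly without replacement via argpartition of
per-iteration uniforms. Randomisation happens at batch granularity
(not per single iteration), which preserves all of the above
properties.

## Bias diagnostics

`bias_table` quantifies how biased each term is *before any experiment
is run*. For a fixed list size it estimates the empirical null mean of
the per-term `union_count`, rounds it half-away-from-zero, and computes
the hypergeometric tail probability of that rounded mean at a fixed,
user-supplied union size `n_for_hypergeom` (a representative union size
for lists of that length). A small p means the standard test would call
the term enriched for a typical *random* list — pure bias. The sign of
`empirical_mean − n·K/N` labels the term `over_targeted` or
`under_targeted`.

`bias_covariate_correlation` then correlates `log10` of these bias
p-values with each term's mean gene covariate (e.g. 3'UTR length)
across terms with at least `min_genes` covariate-annotated genes,
returning the Pearson r and its p-value. On covariate-biased data the
correlation is strongly negative: longer-UTR terms look more
spuriously enriched.

## Synthetic data model

`generate_dataset(SyntheticConfig)` produces a prediction table, an
annotation set and a per-gene covariate:

1. Gene covariates are lognormal with median 1
   (`covariate_log_sd = 0.8`), a stand-in for relative 3'UTR length.
2. miRNA rate factors are lognormal with unit mean
   (`mirna_rate_log_sd = 0.5`).
3. The number of predicted sites for (miRNA i, gene j) is Poisson with
   rate `base_rate · factor_i · covariate_j^bias_strength`. With
   `bias_strength = 0` targeting is uniform; the default `1.0`
   reproduces covariate-driven bias.
4. Term sizes are log-uniform in `[term_size_min, term_size_max]`
   (defaults 10–150). Unplanted terms sample genes uniformly; planted
   terms (default: indices 0–4 with exponent +2.0, 5–9 with −2.0)
   sample genes with weight `covariate^exponent`, and are forced to at
   least `planted_term_size_min = 50` genes so the planted effect is
   not drowned in sampling noise.
5. An optional spike-in `(term_index, n_mirnas, boost)` multiplies the
   site rate of `n_mirnas` randomly chosen miRNAs on the genes of one
   term by `boost`, planting a genuinely enriched signal.
   `spike_in_list` recovers a positive-control input list as the miRNAs
   with the most targets inside that term.

`base_rate = 0.05` was chosen so that a 20-miRNA list covers roughly
60 % of the universe with its target union, matching the regime where
the standard test's bias is most visible while leaving the union
unsaturated. These defaults are frozen; the validation experiments were
not tuned against their own outcomes.

### Validation experiments

`calibration_experiment` draws many random miRNA lists and records, per
term, the fraction rejected at `alpha` by each method (type-I error,
since random lists carry no signal). On unbiased synthetic data both
methods respect the nominal rate (the standard test is conservative due
to discreteness). On biased data the standard test rejects the planted
over-targeted terms for essentially every random list, while the
empirical test stays near 0.05.

Spike-in recovery uses the `union_count` statistic: the planted signal
adds term-gene hits without inflating the union much, and the count
statistic has the sharper null for detecting it. The proportion
statistic is available but less powerful at this scale because small
random unions produce a long right tail of proportions.

## Limitations

- The empirical null treats all miRNAs as exchangeable; if the input
  list is restricted to a family of related miRNAs, a family-aware null
  would be needed.
- The synthetic covariate model is a single multiplicative power law;
  real prediction bias has additional structure (GC content,
  conservation, expression filters).
- `bias_table` evaluates the hypergeometric tail at one fixed `n`;
  reported bias p-values shift with that choice, though rankings are
  stable.
- Exact enumeration is limited to 100 000 subsets; beyond that only
  Monte-Carlo p-values (resolution 1/iterations) are available.
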