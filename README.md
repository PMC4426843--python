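# mirenrich

Bias-aware functional enrichment analysis for miRNA target predictions.

The standard way to interpret a list of miRNAs is to pool their
predicted target genes and run a hypergeometric (Fisher's exact)
over-representation test against gene-set annotations. That test
assumes target genes are a uniform draw from the genome — but target
prediction is strongly biased (genes with long 3'UTRs accumulate
predicted sites), so annotation terms made of heavily-targeted genes
look "enriched" for *any* input list. `mirenrich` implements:

- the standard hypergeometric test (for comparison and as a baseline),
- an **empirical resampling test** whose null is the distribution of
  the statistic over random same-size miRNA lists, which absorbs the
  targeting bias (statistics: union count, union proportion, or a
  binding-site-weighted "multihit" score),
- an exact-enumeration oracle for small problems,
- **bias diagnostics** that quantify per-term targeting bias without
  any input list and correlate it with gene covariates such as 3'UTR
  length,
- a **synthetic data generator** with covariate-driven bias, planted
  biased terms, and spike-in positive controls, plus a calibration
  harness measuring each method's type-I error,
- a `mirenrich` command-line interface over plain TSV/GMT files.

## Quick start

```python
import mirenrich as mr

preds = mr.load_predictions("predictions.tsv")      # mirna <TAB> gene [<TAB> sites]
ann = mr.load_annotations("annotations.gmt")        # GMT gene sets
mirnas = mr.load_mirna_list("list.txt")

standard = mr.standard_enrichment(preds, ann, mirnas)
empirical = mr.empirical_enrichment(preds, ann, mirnas,
                                    n_iterations=1_000_000, seed=1)
print(empirical.significant(fdr=0.05))
empirical.to_tsv("results.tsv")
```

The worked example from the package's reference scenario — 250 of
10 057 predicted targets falling in a 327-gene category over a
15 733-gene universe:

```python
>>> mr.hypergeom_sf(mr.HypergeomParams(k=250, n=10057, K=327, N=15733))
5.965809059990394e-07
```

Why the empirical test matters (output of
`examples/02_empirical_enrichment.py`, a *random* miRNA list on biased
synthetic data — no term is truly enriched):

```
  term   standard p  empirical p  null mean
  T000    1.682e-07      0.09118    0.02918
  T001    1.054e-08       0.1473    0.04598
  T002    6.378e-06        0.125    0.02821
  T003    2.979e-05       0.3899    0.02886
  T004    6.119e-09       0.2414    0.05143
```

The standard test declares all five heavily-targeted terms enriched at
astronomical significance; the empirical test correctly does not. Over
100 random lists (`examples/05_calibration_experiment.py`) the standard
test rejects these terms **100 %** of the time at alpha = 0.05 versus
**3.8 %** for the empirical test, while a genuine spiked-in signal is
still recovered at q < 0.05 (`examples/06_synthetic_and_spike_in.py`).

## Command line

```sh
mirenrich enrich --predictions preds.tsv --annotations ann.gmt \
    --mirnas list.txt --method empirical --iterations 1000000 \
    --seed 1 --out run1            # writes run1.enrichment.tsv + manifest
mirenrich bias --predictions preds.tsv --annotations ann.gmt \
    --list-size 20 --n-for-hypergeom 1800 --iterations 100000 --seed 2 \
    --covariate utr_lengths.tsv --out bias
mirenrich simulate --config config.yaml --out-dir data/
mirenrich calibrate --predictions data/predictions.tsv \
    --annotations data/annotations.gmt --list-size 20 --n-lists 200 \
    --iterations 10000 --seed 3 --out cal
```

Every `enrich` run writes a manifest (input SHA-256 hashes, parameters,
package version) and reruns with the same seed are byte-identical.

## Layout

- `examples/` — six narrative scripts, one per capability; each runs
  standalone in seconds to a couple of minutes.
- `docs/methods.md` — the statistical methods, the synthetic data
  model, performance notes, and the reproducibility contract.
- `scripts/acceptance.py --seed 1 --out results/acceptance.json` —
  end-to-end acceptance metrics (~2 minutes).
- `tests/` — unit, property-based (hypothesis), and acceptance tests.

## File formats

- predictions: TSV `mirna<TAB>gene` (dialect `pairs`) or
  `mirna<TAB>gene<TAB>n_sites` (`pairs_with_counts`); duplicate pairs
  sum their site counts.
- annotations: GMT (`term<TAB>description<TAB>gene...`) or two-column
  pairs; the gene universe defaults to all annotated genes.
- miRNA lists: one name per line, `#` comments allowed.
- aliases: miRBase-style `accession<TAB>name1;name2;...` or two-column
  `old<TAB>new` pairs for renaming/deleting identifiers.
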