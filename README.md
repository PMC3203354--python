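# sigsearch

Phenotype-naive search of gene-expression compendia for **coordinate
differential expression** of an up/down query signature.

Given a query signature (a list of genes induced by a perturbation and a
list of genes repressed by it) and a compendium of expression datasets
(GEO "series"-like groups of samples, each z-score normalized per gene
within the dataset), `sigsearch`:

1. scores **every sample** with a *signature association (SA) score* — a
   standardized Wilcoxon rank-sum statistic comparing the sample's
   relative expression of the up genes against the down genes
   (`W = Σ r_up − n_up(n_up+1)/2`, `SA = (W − μ)/σ` with
   `μ = n_up·n_down/2`, `σ = √(n_up·n_down·(n_up+n_down+1)/12)`;
   two-sided p from a t distribution with `n_up+n_down−2` df);
2. assigns per-sample significance categories (positive / negative / not
   significant) at a Benjamini–Hochberg q-value cutoff (default 0.1),
   pooled across the whole compendium;
3. ranks **datasets** by how strongly their SA-score distribution
   deviates from the pooled background, by a two-sample two-sided
   Kolmogorov–Smirnov test and by an exact Fisher (Freeman–Halton 2×3)
   test on the category counts — a dataset with a *greater* proportion of
   non-significant samples than the background gets Fisher p = 1 — with
   BH FDR across datasets.

The package also ships a synthetic-compendium generator (null datasets,
planted up/down effects, per-gene shuffles, sample subsets) and an
evaluation module (per-sample ROC, power/Type-I sweeps over sample size,
signature size and signature composition).

Real-data intake (CEL processing, RMA, GEO download, probe→gene mapping)
is out of scope: the tool consumes already-summarized gene × sample
matrices.

## CLI

```sh
# validate a signature file
sigsearch validate-signature --signature data/signatures/e2_treatment.tsv

# z-normalize one matrix (per gene, across samples, sd divisor n-1)
sigsearch normalize --matrix expr.tsv --out expr.z.tsv

# generate a synthetic compendium from a YAML spec
sigsearch simulate --spec spec.yaml --out-dir sim/

# score a compendium with a signature and rank datasets
sigsearch query --manifest sim/manifest.tsv \
    --signature data/signatures/e2_treatment.tsv --out-dir out/

# power sweep over sample size / signature size / composition
sigsearch sweep --config sweep.yaml --out-dir sweep_out/
```

`query` writes `sample_scores.tsv` (one row per sample: W, SA, p, q,
category) and `dataset_enrichment.tsv` (one row per dataset: category
counts, ks_p/q, fisher_p/q, direction; sorted ascending by ks_q, then
fisher_q, then dataset_id), plus a `config.yaml` provenance echo and a
`run_summary.json`. Exit codes: 0 success, 2 user-input error, 1
internal error.

A compendium on disk is a tab-delimited manifest
(`dataset_id  platform_id  path  already_normalized`) plus one
tab-delimited matrix per dataset (first column `gene_id`, header row of
sample ids). Signatures are two-column TSV (`gene  direction` with
direction `up`/`down`) or paired GMT records (`<name>_UP`, `<name>_DOWN`).

Example synthetic spec (`spec.yaml`):

```yaml
n_genes: 500
dataset_sizes: [20, 20, 20]
effect_size: 2.0          # added to up genes, subtracted from down genes
affected_fraction: 0.5    # of samples in each perturbed dataset
perturbed_datasets: [0]
seed: 1
signature: {path: data/signatures/e2_treatment.tsv}
```

## Layout

```
src/sigsearch/
  signature.py    signature containers, parsing, writing, subsampling
  compendium.py   dataset/compendium containers, z-normalization, IO
  sa_score.py     per-sample SA scores, p/q-values, categories
  enrichment.py   K-S and exact Fisher dataset tests, FDR, ranking
  synthetic.py    null/planted compendia, gene shuffles, sample subsets
  evaluation.py   ROC, power/Type-I sweeps
  cli.py          command-line interface
tests/            pytest suite (unit, property and acceptance tests)
scripts/acceptance.py
data/signatures/  signature fixtures
```
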