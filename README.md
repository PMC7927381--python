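# radpanels

A toolkit for comparing SNP panels produced by two RAD-seq "building-loci"
pipelines on the same samples, without requiring real sequencing data.

It provides:

- **simdata** — a synthetic-data generator: structured populations
  (Balding–Nichols allele frequencies), true diploid genotypes under
  within-population Hardy–Weinberg proportions, well-separated fixed-length
  tag catalogues, per-pipeline allele-depth matrices (negative-binomial
  coverage, sequencing error) and two genotype callers (a multinomial
  likelihood-ratio caller and a minor-allele-frequency threshold caller),
  with pipeline-specific perturbations: read loss, locus dropout,
  oversplitting and per-cell stacking dropout.
- **filters** — a seven-step SNP filtering cascade with a full audit trail:
  biallelic → minimum coverage (8×) → ≤3 SNPs per locus → minimum allele
  count (3) → per-population call rate (<40% missing) → Hardy–Weinberg
  (exact P < 0.01 in more than half of populations) → first SNP per locus.
- **reconcile** — cross-catalogue locus clustering (greedy best-match
  Hamming clustering of canonically oriented tags, equivalent to
  identity-threshold clustering of equal-length ungapped sequences) and
  construction of the COM (shared) and MER (shared + private) panels.
- **concordance** — genotype-level comparison of two panels at matched
  SNPs: concordant / both-missing / seven mismatch categories, plus
  attribution of one-sided missing genotypes to their mechanistic source
  (below the caller's depth floor, removed by the coverage filter, or
  called-but-uncertain).
- **popgen** — population-genetic statistics from first principles:
  observed and unbiased expected heterozygosity, multi-locus F<sub>IS</sub>
  with percentile-bootstrap CIs, the Weir–Cockerham (1984) multi-locus
  θ estimator of global F<sub>ST</sub>, rarefied allelic richness
  (El Mousadik–Petit), and the biallelic conditional exact
  Hardy–Weinberg test.
- **io / cli** — GENEPOP (4-digit dialect), FASTA catalogues with TSV SNP
  sidecars, depth TSVs, YAML configuration, and a `radpanels` command-line
  interface.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (filter-cascade
oracle, brute-force HWE equivalence, θ recovery, Monte-Carlo allelic
richness, clustering ground-truth recovery, concordance invariants, caller
truth tables, end-to-end identity, mechanism reproduction, GENEPOP
round-trips).

## CLI

```sh
# full workflow: simulate -> filter both pipelines -> reconcile -> compare -> metrics
radpanels full-run --config config.yaml --seed 1 --out out/

# individual stages
radpanels simulate --config sim.yaml --out simdir/
radpanels filter --genepop simdir/raw_STA.genepop --depths simdir/depths_STA.tsv --out filt/
radpanels reconcile --catalog-a a.fasta --catalog-b b.fasta \
    --genepop-a a6.genepop --genepop-b b6.genepop -m 2 --out rec/
radpanels compare --genepop-a com_a.genepop --genepop-b com_b.genepop --out cmp/
radpanels popgen --genepop panel.genepop --bootstrap 1000 --seed 1 --out pg/
```

Example `config.yaml` for `full-run`:

```yaml
simulate:
  n_loci: 500
  n_pops: 2
  pop_sizes: [15, 15]
  fst_sim: 0.05
  cov_mean: 20.0
  cov_dispersion: 3.0
  seq_error: 0.001
  pipeline_a: {read_loss: 0.1}
  pipeline_b: {locus_dropout: 0.05}
  seed: 1
filters:
  min_coverage: 8
  max_snps_per_locus: 3
  mac: 3
  pop_max_missing: 0.40
  hwe_alpha: 0.01
cluster_mismatch: 2
bootstrap: 1000
```

The output directory contains the STA/ALT/COM/MER GENEPOP panels, per-step
filter audits, the cluster table, the concordance and missing-source
tables, per-population metrics, and a manifest logging every threshold and
seed.

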