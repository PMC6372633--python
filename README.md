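# metabotyper

A tested pipeline for linking genotypes, metabolite profiles
("metabotypes") and biomass phenotypes in a factorial plant study design
(genotype x tissue x water regime x replicate):

- **synthetic** — ground-truthed study generator: factorial metadata,
  power-law shoot/root biomass, log-normal feature tables with planted
  tissue / genotype / drought / biomass effects, blank samples, injected
  zeros and outliers with recorded coordinates.
- **qc** — metabolomics feature-table filtering: blank-based background
  removal, zeros-to-missing, per-cell presence filter, Q1/Q3 +- 3xIQR
  outlier nulling (type-7 quartiles, strict fences), log2 transform, and
  per-genotype testability ("ANOVA presence") filtering.
- **allometry** — Bayesian hierarchical log-log shoot-root allometry
  (custom conjugate Gibbs sampler with slice updates for scales, split
  R-hat convergence gate), per-accession root mass fraction, and
  per-accession drought biomass tests with unequal variances.
- **multivariate** — full-factorial PERMANOVA (sequential distance-based
  SS, free-permutation p-values), PCA with iterative low-rank missing-value
  imputation, Ward clustering on squared dissimilarities, tree cutting,
  Baker's gamma with a label-permutation null.
- **differential** — per-genotype drought-vs-control metabolite ANOVAs,
  step-down Holm adjustment, z-standardized log-fold heatmap matrices.
- **coherence** — genotype x metabotype-cluster contingency tables and the
  coherence fraction (replicates of a genotype mapping to one pure cluster).
- **predictive** — cross-validated random-forest biomass prediction with
  genotype indicators, out-of-fold permutation importance, and the
  feature-group ablation RMSE-increase statistic.
- **pipeline / cli** — YAML-configured orchestration with explicit seeds
  and a machine-readable, byte-reproducible run report.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance criteria.
Two of its assertions are intentionally red, documenting impossibilities
in the stated criteria rather than weakened checks:

- `test_criterion4b...`: no pair of binary 4-leaf merge trees attains
  Baker's gamma = -1 (exhaustive enumeration bounds it at -29/60).
- `test_criterion6b...`: with 5 replicates per design cell, the chance of
  an honest value falling outside its own cell's Q3 + 3xIQR fence has an
  order-statistics floor near 3% for every iid continuous noise law, so a
  false-positive rate <= 2% is unattainable without breaking the
  test-calibration properties elsewhere in the suite.

## CLI

```bash
metabotyper all --seed 1 --outdir out/            # full synthetic pipeline
metabotyper simulate --config config.yaml         # run through one stage
metabotyper validate --features f.csv --biomass b.csv
```

Stage verbs (`simulate`, `qc`, `allometry`, `multivariate`,
`differential`, `coherence`, `predict`) run the pipeline through the named
stage. A config YAML round-trips through `PipelineConfig`; every
stochastic stage derives its own named substream from the single top-level
seed, so a rerun with the same config is byte-identical.

## File formats

- Feature table CSV: `sample_id` index, metadata columns
  `plant_id, genotype, tissue, regime, replicate`, then one column per
  feature (`F0001`, ...); empty cells are missing values.
- Blank CSV: same feature columns, `sample_id` index only.
- Biomass CSV: `plant_id, genotype, regime, shoot_dw_g, root_dw_g`.
- Dendrograms are serialized as Newick with heights; reports as JSON.
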