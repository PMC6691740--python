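# otukit

Statistical analysis toolkit for OTU (operational taxonomic unit) count
tables from multi-habitat microbiome surveys: normalization, alpha/beta
diversity, ordination with permutation tests, indicator-taxon detection,
focus-niche enrichment classification, and genus co-occurrence network
inference with keystone identification — plus a synthetic community
generator with planted, recoverable ground truth.

## What it does

- **tables_io** — validated domain types (`CountTable`, `TaxonomyMap`,
  `SampleMetadata`, `PhyloTree`) and TSV / Newick / GraphML+CSV readers
  and writers.
- **synthetic** — generates a multi-cave, four-niche (air / water / rock /
  sediment) survey with planted indicator taxa, latent correlation blocks,
  a hub taxon bridging blocks, and environmental gradients; emits a
  `SyntheticTruth` record for recovery scoring.
- **normalize** — rare-OTU filtering, rarefaction (multivariate
  hypergeometric), cumulative-sum scaling (CSS), relative / CPM
  transforms, genus aggregation.
- **diversity** — Shannon, Chao1 (classic and bias-corrected), Good's
  coverage, Bray–Curtis, weighted UniFrac (raw and normalized), Sørensen
  partitioning into turnover + nestedness, shared/exclusive OTU (Venn)
  counts.
- **ordination** — PCoA (Gower double-centering), one-way PERMANOVA with
  add-one permutation p-values, environmental vector fitting (envfit),
  Spearman rank-correlation screens.
- **indicators** — IndVal.g indicator analysis with permutation tests;
  enrichment/depletion classification of OTUs in a focus niche on
  log2(CPM+1) with Benjamini–Hochberg FDR.
- **network** — genus abundance filtering (>0.05% mean relative
  abundance), Spearman correlation matrices, thresholded co-occurrence
  graphs (ρ > 0.6, adjusted p < 0.01), topology metrics (modularity,
  clustering coefficient, average path length, diameter, average degree),
  Louvain modules, betweenness-centrality keystone ranking, and per-module
  niche preference.
- **pipeline / cli** — a YAML-configured end-to-end run plus per-stage
  subcommands.

## CLI

```bash
# generate a synthetic dataset with ground truth
otukit simulate --out data/ --seed 1

# per-stage commands
otukit alpha     --counts data/counts.tsv --out alpha.tsv
otukit beta      --counts data/counts.tsv --out beta.tsv
otukit permanova --distances beta.tsv --metadata data/metadata.tsv --group niche
otukit indval    --counts data/counts.tsv --metadata data/metadata.tsv --out indval.tsv
otukit enrich    --counts data/counts.tsv --metadata data/metadata.tsv --focus air --out enrich.tsv
otukit network   --counts data/counts.tsv --taxonomy data/taxonomy.tsv \
                 --metadata data/metadata.tsv --out-prefix net

# full pipeline from a config (see examples/run.yaml)
otukit run --config examples/run.yaml --seed 1 --out results/
```

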