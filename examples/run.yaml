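# Annotated pipeline configuration for `otukit run --config run.yaml`.
# Every key is optional; shown values are the defaults unless noted.

out_dir: otukit_run        # all stage outputs and report.json land here
seed: 0                    # root seed; per-stage seeds derive from it

# ---- inputs -----------------------------------------------------------------
# Either point at files ...
# counts: counts.tsv       # TSV count table
# orientation: taxa_rows   # or samples_rows
# taxonomy: taxonomy.tsv   # taxon_id + 7 rank columns
# metadata: metadata.tsv   # sample_id, cave_id, niche, factors (NA allowed)
# tree: tree.nwk           # rooted Newick (needed for beta_metric: wunifrac)
# truth: truth.json        # optional planted ground truth for recovery scores
# ... or generate a synthetic dataset (overrides the file inputs):
synthetic:
  n_caves: 8
  samples_per_cave_per_niche: 4   # 8 caves x 4 niches x 4 = 128 samples
  n_taxa: 600
  depth: 30000                    # reads per sample
  indicator_effect: 2.0           # log-scale shift of planted indicators
  n_blocks: 4                     # planted correlation modules
  block_size: 12
  block_rho: 0.7                  # latent within-block correlation
  hub_links: 2                    # blocks bridged by the planted hub

# ---- normalization ----------------------------------------------------------
rare_otu_threshold: 1.0e-5  # drop OTUs below this table-wide relative abundance
rarefaction_depth: null     # null = minimum sample total
css_quantile: 0.5

# ---- diversity / ordination -------------------------------------------------
beta_metric: braycurtis     # or wunifrac (requires a tree)
n_permutations: 999         # PERMANOVA / envfit / IndVal permutations
envfit_axes: 2

# ---- indicators and enrichment ---------------------------------------------
indval_stat_threshold: 0.6
indval_p_threshold: 0.05
enrich_focus: air
enrich_n_permutations: 2000

# ---- co-occurrence networks -------------------------------------------------
network_rho_min: 0.6              # Spearman threshold (positive-only)
network_p_max: 0.01
network_abundance_threshold: 0.0005   # mean relative abundance > 0.05%
network_fdr: true                 # Benjamini-Hochberg over all tested pairs
network_scopes: [overall, air, water, rock, sediment]
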