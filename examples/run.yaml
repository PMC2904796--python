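# Full-pipeline configuration for `chronoscreen run --config examples/run.yaml`.
# With simulate: true the screen is generated; point intensities_path /
# cfu_path (and set simulate: false) to analyse real tables instead.
outdir: chronoscreen_run
seed: 1
simulate: true
screen:
  n_strains: 1000
  seed: 1
# analysis thresholds (defaults shown)
k_factor: 2.0          # background exclusion: intensity < k * background at every day
rsme_percentile: 90.0  # replicate-concordance exclusion
k_clusters: 10
theta_short: 0.5       # log2-unit class boundary
theta_long: 0.5
permutations: 500
pi0_lambda: 0.5
q_cutoff: 0.1
enrich_alpha: 0.01
# annotation_path: annotations.tsv   # two-column gene<TAB>term to enable enrichment
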