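# Synthetic-study configuration (defaults shown; all keys optional).
# Generate inputs with:  caddforge synth --config synth.yaml --out fixtures/

seed: 11
genome_length: 200000
n_chroms: 1
composition: [0.25, 0.25, 0.25, 0.25]   # A, C, G, T
divergence: 0.01            # ancestor/reference per-site substitution rate
transition_bias: 2.0        # transitions weighted 2x transversions
unaligned_fraction: 0.1     # genome fraction left uncovered by MAF blocks
n_blocks: 4                 # alignment blocks per chromosome (one on '-')
n_pop_sites: 600
beta_a: 0.5                 # allele-frequency spectrum Beta(a, b)
beta_b: 0.5

# Planted class-conditional features (numeric: Normal(class * beta, sigma)).
numeric_features:
  - {name: cons_a, beta: 1.0, sigma: 1.0, fmt: bedgraph}
  - {name: cons_b, beta: 0.8, sigma: 1.0, missing_fraction: 0.1, imputation: mean_from_simulated}
  - {name: cons_c, beta: 0.5, sigma: 1.0, missing_fraction: 0.1}
  - {name: cons_d, beta: 0.3, sigma: 1.0, imputation: fixed, fixed_value: 0.0}
categorical_feature:
  name: state
  levels: [reg_active, reg_weak, background]
  p_derived: [0.2, 0.3, 0.5]
  p_simulated: [0.45, 0.3, 0.25]
  missing_fraction: 0.0

oracle_draws: 1000000       # Monte-Carlo size for the Bayes-AUC oracle
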