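# Example configuration: synthetic cohort, full analysis.
# Run:  msmediate run --config examples/config.yaml --out results/
seed: 20230101

simulation:
  n_individuals: 5000
  n_waves: 9
  # missingness injected at the generator's default MAR rates;
  # set wave_nonresponse: 0 and missing_rates: {} for a complete panel

imputation:
  m: 20                 # completed datasets
  n_chain_iterations: 10
  k_pmm: 5

analysis:
  mode: full            # full | transition-gain | transition-loss
  n_boot: 1000          # bootstrap re-samplings
  m: 20
  complete_case: false

# clip combined weights at empirical percentiles (recommended for samples
# below ~5000 persons); delete this block to disable truncation
truncation:
  lower_pct: 1
  upper_pct: 99
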