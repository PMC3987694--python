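# Demo configuration for the end-to-end pipeline:
#   spatialprev all --config examples/demo.yaml --outdir run --seed 7
# Simulates a 20-area survey with a strong spatial field, fits all four
# hierarchical models, maps the best by DIC and scans for clusters.
seed: 7
simulate:
  rows: 4
  cols: 5
  psus_per_area: 3
  respondents_per_psu: 25
  weight_dispersion: 0.2
  truth:
    beta0: -1.0
    tau_s: 0.5     # strong spatial structure
    tau_u: 10.0
model:
  models: [1, 2, 3, 4]
  iterations: 4000
  burn_in: 1500
  thin: 3
  prior_a: 0.5
  prior_b: 0.0005
  beta_prior_precision: 1.0e-4
scan:
  directions: [high, low]
  max_fraction: 0.5
  replications: 999
  alpha: 0.05
  use_weights: false
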