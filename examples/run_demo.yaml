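# Demo configuration for `alpsflow run --config examples/run_demo.yaml`.
# Completes in well under a minute on one CPU.
master_seed: 42
out_dir: alpsflow_demo
phantom:
  n_per_group: 2
  snr: 30.0
  noise: rician
  grid_shape: [12, 12, 12]
  n_directions: 32
cohort: {}          # defaults: PD n=51, NC n=30 with the study's ALPS distributions
analysis:
  alpha: 0.05
  n_boot: 2000
  ci_level: 0.95
  mediators: [anterior_cingulate_gyrus, orbital_inferior_frontal_gyrus]
  yates: false
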