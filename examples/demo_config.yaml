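# Desk-scale demo pipeline: `mirtarget run --config examples/demo_config.yaml`
out_dir: scratch/demo_run
seed: 7
simulation:
  n_cohorts: 4
  n_mirnas: 30
  n_genes: 120
  samples_per_cohort: 80
  n_planted_training: 60
  n_planted_heldout: 25
  n_planted_undiscovered: 25
ensemble:
  downsample_rates: [0.05, 0.2, 1.0]
  n_models: 10
n_perturbations: 2
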