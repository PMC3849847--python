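# Small demonstration pipeline configuration.
# Run:  comorbval all --config examples/demo_config.yaml --out results/demo
out_dir: results/demo
seed: 1
windows: [index, 1, 2, 5, 10, 15]
strata: [indigenous_derived]
drop_not_recorded: false
entry_p: 0.05
simulation:
  n_patients_per_era:
    ICD9: 400
    ICD10: 500
  history_years: 16
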