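# Langevin-histogram landscape versus the mean-field landscape
kind: oracle_check
name: oracle_check
schema_version: 1
projection: [cortex, thalamus]
options:
  D_input: 0.8
  nx: 100
  ny: 100
  n_snapshots: 100
  dt: 0.02
  duration: 3000.0
  n_walkers: 64
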