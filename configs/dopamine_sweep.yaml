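# Barrier height, average flux, period and EPR across the oscillatory block
kind: dopamine_sweep
name: dopamine_sweep
schema_version: 1
projection: [cortex, thalamus]
options:
  D_levels: [0.70, 0.75, 0.80, 0.85, 0.90, 0.95, 1.00, 1.05]
  nx: 200
  ny: 200
  n_snapshots: 200
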