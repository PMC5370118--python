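# Global sensitivity of barrier and flux to the labelled connections
kind: sensitivity
name: sensitivity
schema_version: 1
projection: [cortex, thalamus]
options:
  D_input: 0.95
  percent_grid: [-50, -40, -30, -20, -10, 0, 10, 20, 30, 40, 50]
  nx: 100
  ny: 100
  n_snapshots: 100
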