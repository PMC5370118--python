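# Decoupled DBS of GPe: somatic inhibition with efferent activation
kind: dbs
name: dbs_decoupled_GPe
schema_version: 1
projection: [cortex, thalamus]
options:
  target: GPe
  mode: decoupled
  D_input: 0.9
  offsets: [0.0, -0.25, -0.5, -0.75, -1.0, -1.25, -1.5, -1.75, -2.0]
  gains: [1.0, 1.04, 1.08, 1.12, 1.17, 1.21, 1.25, 1.29, 1.33]
  nx: 100
  ny: 100
  n_snapshots: 100
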