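# Direct-inhibition DBS of STN: constant negative somatic input
kind: dbs
name: dbs_direct_STN
schema_version: 1
projection: [cortex, thalamus]
options:
  target: STN
  mode: direct_inhibition
  D_input: 0.9
  offsets: [0.0, -0.1, -0.2, -0.3, -0.4, -0.5, -0.6, -0.7, -0.8]
  nx: 100
  ny: 100
  n_snapshots: 100
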