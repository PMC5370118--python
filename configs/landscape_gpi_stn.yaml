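# Replicate ring landscape on the GPi-STN projection
kind: landscape
name: landscape_gpi_stn
schema_version: 1
projection: [GPi_SNr, STN]
options:
  D_input: 0.8
  nx: 200
  ny: 200
  n_snapshots: 200
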