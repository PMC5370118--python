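# Mono-stable landscape at healthy dopamine (cortex-thalamus projection)
kind: landscape
name: landscape_normal_state
schema_version: 1
projection: [cortex, thalamus]
options:
  D_input: 1.4
  nx: 200
  ny: 200
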