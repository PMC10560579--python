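simulate:
  duration_s: 120.0
  regions: [cortex, striatum]
n_shuffle: 200
n_perm: 1000
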