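# Cold (17 degC): birds crowd under white light.
# Demo preset mirroring the qualitative cold-condition occupancy pattern.
thermal: cold
light_weights:
  white: 0.58
  red: 0.29
  green: 0.13
activity_scale:
  hot: 0.7
  neutral: 1.0
  cold: 1.0
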