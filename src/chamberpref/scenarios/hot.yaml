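# Heat stress (35 degC): preference flattens toward uniform and activity
# drops — birds spread out and move less.  Demo preset only.
thermal: hot
light_weights:
  white: 0.36
  red: 0.31
  green: 0.33
activity_scale:
  hot: 0.7
  neutral: 1.0
  cold: 1.0
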