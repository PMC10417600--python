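# Thermoneutral (24 degC): birds favour white, then red, avoid green.
# Weights chosen to mirror the qualitative occupancy pattern at comfort
# temperature; they are demo presets, not measurements of real hens.
thermal: neutral
light_weights:
  white: 0.45
  red: 0.37
  green: 0.18
activity_scale:
  hot: 0.7
  neutral: 1.0
  cold: 1.0
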