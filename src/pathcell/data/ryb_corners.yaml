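# RYB blending corner colors (RGB in [0,1]) for trilinear interpolation.
# Tuned for data visualization: yellow darkened toward gold and blue
# lightened toward azure (the pure primaries read too light / too dark),
# with lightness decreasing along every RYB axis so deeper color always
# means more signal. Validated at load; override with a file of the same
# shape to retune.
corners:
  white:  [1.00, 1.00, 1.00]
  red:    [0.96, 0.32, 0.29]
  yellow: [0.98, 0.80, 0.15]
  blue:   [0.27, 0.55, 0.83]
  orange: [0.80, 0.42, 0.05]
  green:  [0.18, 0.55, 0.23]
  purple: [0.45, 0.23, 0.52]
  black:  [0.16, 0.12, 0.11]
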