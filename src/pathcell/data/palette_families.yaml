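# Preset palette families: perceptual constraint boxes (CIELAB / LCh).
# hue_range in degrees (lo > hi means the interval wraps through 0),
# lightness_range in L*, chroma_range in C*. Each family regenerates
# deterministically from its fixed seed.
families:
  default:
    hue_range: [0.0, 360.0]
    lightness_range: [35.0, 70.0]
    chroma_range: [25.0, 70.0]
    seed: 101
  light:
    hue_range: [0.0, 360.0]
    lightness_range: [65.0, 88.0]
    chroma_range: [15.0, 45.0]
    seed: 102
  red:
    hue_range: [10.0, 45.0]
    lightness_range: [40.0, 70.0]
    chroma_range: [30.0, 70.0]
    seed: 103
  yellow:
    hue_range: [70.0, 110.0]
    lightness_range: [60.0, 85.0]
    chroma_range: [30.0, 70.0]
    seed: 104
  green:
    hue_range: [115.0, 165.0]
    lightness_range: [40.0, 75.0]
    chroma_range: [25.0, 65.0]
    seed: 105
  blue:
    hue_range: [230.0, 300.0]
    lightness_range: [35.0, 70.0]
    chroma_range: [20.0, 60.0]
    seed: 106
  purple:
    hue_range: [300.0, 345.0]
    lightness_range: [35.0, 70.0]
    chroma_range: [20.0, 60.0]
    seed: 107
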