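# Fibrillatory fixture with a patchy dominant-frequency field:
# 5 Hz on the left half of the array, 8 Hz on the right.
seed: 1
layout: {rows: 16, cols: 16, spacing_mm: 3.5}
scenario:
  rhythm: fibrillatory
  df_field:
    default_hz: 5.0
    jitter: 0.1
    patches:
      - {half: right, hz: 8.0}
duration_s: 8.0
df_band_hz: [3.0, 15.0]
ri_threshold: 0.2
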