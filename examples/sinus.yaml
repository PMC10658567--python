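# Default sinus-rhythm demo: plane wave at 1.04 m/s, 114 bpm, 16x16 array.
seed: 1
layout: {rows: 16, cols: 16, spacing_mm: 3.5}
scenario:
  rhythm: sinus
  cv_m_per_s: 1.04
  rate_bpm: 114.0
  edge: left
sample_rate_hz: 2048.0
duration_s: 2.0
noise_rms_mv: 0.006
band_hz: [1.0, 400.0]
n_bands: 15
frame_interval_ms: 5.0
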