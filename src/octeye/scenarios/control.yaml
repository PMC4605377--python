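# Control arm: isotonic drops only, 60 min imaged every 5 min.
name: control
preset: mouse
baseline_repeats: 5
phases:
  - osmolality: 250
    duration_min: 60
    frames_per_min: 0.2
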