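# Static calibration model eye (manufacturer anterior-segment dimensions):
# five repeat acquisitions, no challenge.
name: model_eye
preset: model_eye
baseline_repeats: 5
phases:
  - osmolality: 250
    duration_min: 5
    frames_per_min: 1
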