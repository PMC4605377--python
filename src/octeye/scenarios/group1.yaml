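# Group I: strong hypertonic challenge (Drop-1000) and reversal.
# Challenge-phase asymptotes encode the observed peak changes: CCT -20.7 %,
# ACD -11.5 %, CRD -2.3 %, LT unchanged, LSI +28.8 %, iris sag 28.6 -> 48.2 um.
name: group1
preset: mouse
baseline_repeats: 5
phases:
  - osmolality: 250
    duration_min: 10
    frames_per_min: 0.2
  - osmolality: 1000
    duration_min: 13
    frames_per_min: 1
    responses:
      CCT: {amplitude: -0.207, tau_min: 2.0}
      ACD: {amplitude: -0.115, tau_min: 2.5}
      CRD: {amplitude: -0.023, tau_min: 2.5}
      LT: {amplitude: 0.0, tau_min: 2.0}
      LSI: {amplitude: 0.288, tau_min: 2.5}
      IRIS_SAG: {amplitude: 0.68531, tau_min: 2.0}
  - osmolality: 250
    duration_min: 40
    frames_per_min: 0.2
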