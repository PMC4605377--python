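# Group II: milder hypertonic challenge (Drop-500) and reversal.
# Magnitudes half of Group I, slightly slower time constants.
name: group2
preset: mouse
baseline_repeats: 5
phases:
  - osmolality: 250
    duration_min: 10
    frames_per_min: 0.2
  - osmolality: 500
    duration_min: 13
    frames_per_min: 1
    responses:
      CCT: {amplitude: -0.1035, tau_min: 2.5}
      ACD: {amplitude: -0.0575, tau_min: 2.8}
      CRD: {amplitude: -0.0115, tau_min: 2.8}
      LT: {amplitude: 0.0, tau_min: 2.5}
      LSI: {amplitude: 0.144, tau_min: 2.8}
      IRIS_SAG: {amplitude: 0.343, tau_min: 2.5}
  - osmolality: 250
    duration_min: 40
    frames_per_min: 0.2
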