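# Group III: hypotonic challenge (Drop-100) and reversal; opposite signs,
# slower rate, no lens-scattering change; iris bows posteriorly (concave).
name: group3
preset: mouse
baseline_repeats: 5
phases:
  - osmolality: 250
    duration_min: 10
    frames_per_min: 0.2
  - osmolality: 100
    duration_min: 24
    frames_per_min: 0.3333333333333333
    responses:
      CCT: {amplitude: 0.12, tau_min: 4.0}
      ACD: {amplitude: 0.06, tau_min: 4.0}
      CRD: {amplitude: 0.015, tau_min: 4.0}
      LT: {amplitude: 0.0, tau_min: 4.0}
      LSI: {amplitude: 0.0, tau_min: 4.0}
      IRIS_SAG: {amplitude: -1.86014, tau_min: 4.0}
  - osmolality: 250
    duration_min: 24
    frames_per_min: 0.3333333333333333
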