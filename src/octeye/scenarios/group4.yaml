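# Group IV: iris-morphology arm. Hypertonic then hypotonic, one acquisition
# at the end of each 20-min challenge. Iris sag asymptotes encode the
# observed iris curvatures: 28.6 um (isotonic) -> 48.2 um (hypertonic)
# -> -24.6 um (hypotonic, concave).
name: group4
preset: mouse
baseline_repeats: 5
phases:
  - osmolality: 250
    duration_min: 10
    frames_per_min: 0.2
  - osmolality: 1000
    duration_min: 20
    frames_per_min: 0.05
    responses:
      CCT: {amplitude: -0.207, tau_min: 2.0}
      ACD: {amplitude: -0.115, tau_min: 2.5}
      CRD: {amplitude: -0.023, tau_min: 2.5}
      LT: {amplitude: 0.0, tau_min: 2.0}
      LSI: {amplitude: 0.288, tau_min: 2.5}
      IRIS_SAG: {amplitude: 0.68531, tau_min: 2.0}
  - osmolality: 100
    duration_min: 20
    frames_per_min: 0.05
    responses:
      CCT: {amplitude: 0.12, tau_min: 4.0}
      ACD: {amplitude: 0.06, tau_min: 4.0}
      CRD: {amplitude: 0.015, tau_min: 4.0}
      LT: {amplitude: 0.0, tau_min: 4.0}
      LSI: {amplitude: 0.0, tau_min: 4.0}
      IRIS_SAG: {amplitude: -1.86014, tau_min: 2.5}
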