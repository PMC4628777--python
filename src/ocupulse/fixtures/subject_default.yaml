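# Default acquisition: 90 frames at 22.7 Hz (3.96 s), desk-scale frame size.
acquisition:
  n_frames: 90
  frame_rate: 22.7
geometry:
  n_rows: 200
  n_cols: 160
  cornea_apex_row: 40.0
  cornea_thickness: 12.0
  cornea_curvature: 0.002
  iris_base_row: 120.0
  iris_slope: 0.15
  band_intensity_cornea: 0.25
  band_intensity_iris: 0.55
  background_intensity: 0.05
motion:
  breathing: {frequency: 0.25, amplitude: 2.0, phase: 0.0}
  cardiac: {frequency: 1.25, phase: 0.0, harmonic_amplitudes: [1.0]}
  cornea_gain: 1.0
  iris_gain: 1.0
  lateral_drift: {amplitude: 0.0, frequency: 0.0}
noise:
  speckle_looks: 4
  additive_sigma: 0.01
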