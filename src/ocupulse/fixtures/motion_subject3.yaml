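# Subject-3-like motion: breathing at 0.25 Hz, cardiac fundamental 1.25 Hz
# with a harmonic comb at multiples of 1.25 Hz (orders 1, 2, 3 and 5 — the
# 4th multiple at 5 Hz is absent); highest injected harmonic 6.25 Hz stays
# below the 11.35 Hz Nyquist of a 22.7 Hz acquisition.
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
  iris_step: {step_col: 110, step_height: -6.0}
  band_intensity_cornea: 0.25
  band_intensity_iris: 0.55
  background_intensity: 0.05
motion:
  breathing: {frequency: 0.25, amplitude: 2.0, phase: 0.0}
  cardiac: {frequency: 1.25, phase: 0.0, harmonic_amplitudes: [1.0, 0.5, 0.35, 0.0, 0.25]}
  cornea_gain: 1.0
  iris_gain: 1.0
  lateral_drift: {amplitude: 0.0, frequency: 0.0}
noise:
  speckle_looks: 4
  additive_sigma: 0.01
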