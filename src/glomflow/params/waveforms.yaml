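# Published piecewise receptor-conductance constants (version 1).
# Times in ms; amplitudes in the dimensionless units of the original fits.
weak:
  A_amp: 0.0415
  A_half: 190.0
  A_slope: 40.0
  B_amp: 0.017
  B_shift: 200.55
  B_slope: 100.14
  B_window: 1500.0
  C_base: 0.041
  C_offset: 0.010774
  C_amp: 0.03674
  C_tau: 1232.7
  C_onset: 190.0
strong:
  A_amp: 0.08
  A_half: 90.0
  A_slope: 20.0
  B_amp: 0.0482
  B_shift: 606.55
  B_slope: 240.14
  B_window: 2500.0
  C_base: 0.08
  C_offset: 0.04474
  C_amp: 0.03674
  C_tau: 454.54
  C_onset: 190.0
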