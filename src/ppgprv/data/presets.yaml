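# Scenario presets: ECG-derived cohort means for the four study
# scenarios (3-min recordings at 40 Hz, ~1% sample dropout).
# target_* values in ms; respiration_rate in breaths/min.
sitting:
  target_mean_ibi: 757.16
  target_sdnn: 47.94
  target_rmssd: 38.33
  respiration_rate: 15.0
  rsa_amplitude: 0.0
  dropout_rate: 0.01
  duration: 180.0
sitting_deep_breathing:
  target_mean_ibi: 733.66
  target_sdnn: 63.15
  target_rmssd: 46.55
  respiration_rate: 10.0
  rsa_amplitude: 40.0
  dropout_rate: 0.01
  duration: 180.0
standing:
  target_mean_ibi: 733.66
  target_sdnn: 63.15
  target_rmssd: 24.39
  respiration_rate: 15.0
  rsa_amplitude: 0.0
  dropout_rate: 0.01
  duration: 180.0
supine:
  target_mean_ibi: 851.51
  target_sdnn: 48.0
  target_rmssd: 49.52
  respiration_rate: 15.0
  rsa_amplitude: 0.0
  dropout_rate: 0.01
  duration: 180.0
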