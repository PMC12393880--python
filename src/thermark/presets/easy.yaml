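# Well-separated deposits, mouse kept clear of deposit sites.
width: 160
height: 120
fps: 8.66
habituation_s: 120.0
trial_s: 120.0
gap_s: 0.0
floor_temp_C: 25.0
floor_sigma_C: 0.3
wall_temp_C: 22.0
mouse_temp_C: 35.0
mouse_radius_px: 7.0
step_sigma_px: 1.8
dwell_prob: 0.05
noise_sigma_C: 0.05
nuc_amp_C: 0.3
blackbody_temp_C: 37.0
drift_amp_C: 0.3
drift_period_s: 120.0
avoid_events: always
clearance_px: 20.0
schedule:
  n_urine: 5
  n_feces: 5
  time_range_s: [25.0, 75.0]
  min_separation_px: 30.0
  urine:
    radius_px: [3.0, 5.0]
    peak_dT_C: [9.0, 11.0]
    tau_s: [35.0, 55.0]
    dark_offset_C: 0.5
  feces:
    radius_px: [1.2, 2.0]
    peak_dT_C: [9.0, 11.0]
    tau_s: [30.0, 60.0]
    dark_offset_C: 0.5
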