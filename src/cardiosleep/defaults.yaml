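# Default parameters of the synthetic cohort generator.
#
# Stage-dependent physiology values are synthetic conventions chosen to give
# a staging model realistic (but clean) cardiorespiratory cues; they are the
# single editable source for the generator's defaults.

physio:
  # beats/min per stage; ordering wake > REM > N1N2 > N3
  hr_by_stage: {WAKE: 65.0, N1N2: 60.0, N3: 55.0, REM: 62.0}
  # SD of the inter-beat interval in ms (beat-to-beat variability)
  hrv_sd_by_stage: {WAKE: 60.0, N1N2: 50.0, N3: 30.0, REM: 70.0}
  # breaths/min per stage
  resp_rate_by_stage: {WAKE: 14.0, N1N2: 15.0, N3: 13.0, REM: 16.0}
  # unitless fractional breathing-rate jitter; REM is the most irregular
  resp_irregularity_by_stage: {WAKE: 0.08, N1N2: 0.04, N3: 0.02, REM: 0.12}
  # unit vector of chest-wall respiratory displacement in the device frame
  resp_axis: [0.0, 0.0, 1.0]
  # amplitude of respiratory chest-wall acceleration, in g
  resp_amplitude_g: 0.01
  # posture (gravity re-orientation) events per hour
  posture_change_rate: 1.5
  # wake-time movement bursts per hour of wake
  wake_motion_burst_rate: 30.0
  # respiratory sinus arrhythmia: RR modulation amplitude in seconds
  rsa_amp_sec: 0.02

hypnogram:
  mean_cycle_min: 90.0
  sol_min: 16.7          # sleep-onset latency target (minutes)
  n3_front_loading: 0.02 # per-cycle decay of N3 entry probability
  # stationary stage mix of the transition chain (fractions over
  # WAKE/N1N2/N3/REM); matches a home-EEG insomnia cohort's label mix
  stationary: {WAKE: 0.1208, N1N2: 0.3234, N3: 0.3561, REM: 0.1996}
  # per-epoch switching rate of the chain (sets mean bout lengths)
  switching_rate: 0.05

cohort:
  n_participants: 13
  baseline_tib_min: 461.0      # mean baseline time in bed, minutes
  tib_between_sd_min: 25.0     # between-participant TIB spread
  tib_within_sd_min: 8.0       # night-to-night TIB spread
  srt_tib_restriction_min: 120.0
  n3_trend_per_night: -1.0     # percentage points of sleep per night
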