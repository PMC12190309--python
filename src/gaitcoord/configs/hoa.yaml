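# Default synthetic-cohort parameters: healthy older adults (HOA).
# Speeds and excursions follow published descriptive statistics for this
# population walking a short straight track at three instructed speeds.
group: HOA
n_participants: 19
passes_per_speed: 5
fs: 200.0
seed: 0
noise:
  accel_sd: 0.05    # m/s^2
  gyro_sd: 0.005    # rad/s
  mag_sd: 0.5       # uT
conditions:
  slow:
    speed_mean: 0.67        # m/s
    speed_sd: 0.17
    hip_exc_mean: 34.6      # degrees
    hip_exc_sd: 7.4
    knee_exc_mean: 59.6
    knee_exc_sd: 8.1
    lag_mean_deg: 60.0      # mean hip-knee phase lag
    lag_sd_deg: 10.0        # trial-to-trial lag SD (generative analogue of DP)
    cadence_spm: 86.0       # steps/min -> stride time 1.40 s
    strides_per_pass: 5
  preferred:
    speed_mean: 1.07
    speed_sd: 0.21
    hip_exc_mean: 40.5
    hip_exc_sd: 7.6
    knee_exc_mean: 65.2
    knee_exc_sd: 8.6
    lag_mean_deg: 60.0
    lag_sd_deg: 10.0
    cadence_spm: 109.0
    strides_per_pass: 3
  fast:
    speed_mean: 1.45
    speed_sd: 0.27
    hip_exc_mean: 45.2
    hip_exc_sd: 7.6
    knee_exc_mean: 62.6
    knee_exc_sd: 9.7
    lag_mean_deg: 60.0
    lag_sd_deg: 10.0
    cadence_spm: 126.0
    strides_per_pass: 3
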