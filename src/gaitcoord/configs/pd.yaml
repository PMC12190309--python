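# Default synthetic-cohort parameters: people with Parkinson's disease (PD).
# Slightly smaller mean phase lag (more in-phase coupling) and larger
# trial-to-trial lag SD than the HOA defaults emulate the trend-level group
# differences reported for this population; speeds and excursions follow
# published descriptive statistics.
group: PD
n_participants: 24
passes_per_speed: 5
fs: 200.0
seed: 0
noise:
  accel_sd: 0.05    # m/s^2
  gyro_sd: 0.005    # rad/s
  mag_sd: 0.5       # uT
conditions:
  slow:
    speed_mean: 0.65
    speed_sd: 0.17
    hip_exc_mean: 30.2
    hip_exc_sd: 7.4
    knee_exc_mean: 53.4
    knee_exc_sd: 8.4
    lag_mean_deg: 55.0
    lag_sd_deg: 12.0
    cadence_spm: 86.0
    strides_per_pass: 5
  preferred:
    speed_mean: 0.97
    speed_sd: 0.18
    hip_exc_mean: 34.5
    hip_exc_sd: 7.3
    knee_exc_mean: 55.3
    knee_exc_sd: 9.2
    lag_mean_deg: 55.0
    lag_sd_deg: 12.0
    cadence_spm: 109.0
    strides_per_pass: 3
  fast:
    speed_mean: 1.19
    speed_sd: 0.34
    hip_exc_mean: 39.5
    hip_exc_sd: 10.5
    knee_exc_mean: 55.5
    knee_exc_sd: 9.7
    lag_mean_deg: 55.0
    lag_sd_deg: 12.0
    cadence_spm: 126.0
    strides_per_pass: 3
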