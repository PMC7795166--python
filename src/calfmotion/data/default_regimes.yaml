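# Default per-behaviour signal regimes and time-budget prevalences for the
# synthetic collar-IMU simulator.  Amplitudes are in g (accelerometer) and
# degrees/second (gyroscope); bout durations in seconds.  These values are
# design choices producing the qualitative contrasts the pipeline relies on
# (play = short bursty high-amplitude bouts, rumination = slow periodic jaw
# movement, non-active lying = quiet); they are NOT estimates of real calf
# signal statistics.
sample_rate: 100
prevalences:
  non-active lying: 0.4500
  active lying: 0.2000
  ruminating: 0.1800
  self-grooming: 0.0500
  nutritive suckling: 0.0400
  non-nutritive suckling: 0.0773
  locomotor play: 0.0027
regimes:
  non-active lying:
    accel_amplitude: 0.0
    gyro_amplitude: 0.0
    oscillation_freq: 0.0
    burst_rate: 0.0
    accel_noise_sd: 0.02
    gyro_noise_sd: 1.0
    mean_bout_s: 240.0
    sd_bout_s: 120.0
  active lying:
    accel_amplitude: 0.10
    gyro_amplitude: 8.0
    oscillation_freq: 0.5
    burst_rate: 0.06
    burst_accel: 0.9
    burst_gyro: 90.0
    accel_noise_sd: 0.05
    gyro_noise_sd: 4.0
    mean_bout_s: 120.0
    sd_bout_s: 60.0
  ruminating:
    accel_amplitude: 0.06
    gyro_amplitude: 15.0
    oscillation_freq: 1.2
    burst_rate: 0.0
    accel_noise_sd: 0.03
    gyro_noise_sd: 2.0
    mean_bout_s: 300.0
    sd_bout_s: 150.0
  self-grooming:
    accel_amplitude: 0.42
    gyro_amplitude: 55.0
    oscillation_freq: 2.6
    burst_rate: 0.25
    burst_accel: 1.0
    burst_gyro: 130.0
    accel_noise_sd: 0.17
    gyro_noise_sd: 17.0
    mean_bout_s: 20.0
    sd_bout_s: 10.0
  nutritive suckling:
    accel_amplitude: 0.20
    gyro_amplitude: 30.0
    oscillation_freq: 2.5
    burst_rate: 0.02
    burst_accel: 0.8
    burst_gyro: 80.0
    accel_noise_sd: 0.10
    gyro_noise_sd: 8.0
    mean_bout_s: 180.0
    sd_bout_s: 60.0
  non-nutritive suckling:
    accel_amplitude: 0.18
    gyro_amplitude: 25.0
    oscillation_freq: 3.0
    burst_rate: 0.10
    burst_accel: 1.0
    burst_gyro: 110.0
    accel_noise_sd: 0.10
    gyro_noise_sd: 8.0
    mean_bout_s: 60.0
    sd_bout_s: 30.0
  locomotor play:
    accel_amplitude: 0.55
    gyro_amplitude: 70.0
    oscillation_freq: 3.0
    burst_rate: 0.4
    burst_accel: 1.2
    burst_gyro: 150.0
    accel_noise_sd: 0.20
    gyro_noise_sd: 20.0
    mean_bout_s: 6.0
    sd_bout_s: 3.0
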