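# Built-in disease profiles: per-group generative parameters.
# Rates, pitch, T1, polarity and transmission follow the published group
# means +/- SD (between-patient); the half-period count follows the
# zero-crossing counts via the zxs = n + 1 convention; amplitude decay is
# set so the half-periods retained above the 10% floor match that count.
IPF:
  name: IPF
  insp_crackle_rate_mean: 18.0
  insp_crackle_rate_sd: 14.0
  exp_crackle_rate_mean: 9.0
  exp_crackle_rate_sd: 7.0
  pitch_mean: 416.0
  pitch_sd: 88.0
  t1_mean: 1.2
  t1_sd: 0.2
  n_half_periods_mean: 8.0
  n_half_periods_sd: 2.0
  t2_over_t1: 1.2
  amplitude_decay: 0.72
  positive_polarity_fraction: 0.74
  positive_polarity_sd: 0.13
  transmission_level: 0.16
  transmission_sd: 0.05
  amplitude_mean: 9.0
  amplitude_sd: 9.0
  spatial_pattern: uniform
  noise_rms: 0.12
CHF:
  name: CHF
  insp_crackle_rate_mean: 7.0
  insp_crackle_rate_sd: 5.0
  exp_crackle_rate_mean: 5.0
  exp_crackle_rate_sd: 3.0
  pitch_mean: 302.0
  pitch_sd: 64.0
  t1_mean: 1.4
  t1_sd: 0.2
  n_half_periods_mean: 5.0
  n_half_periods_sd: 1.0
  t2_over_t1: 1.5
  amplitude_decay: 0.58
  positive_polarity_fraction: 0.67
  positive_polarity_sd: 0.20
  transmission_level: 0.23
  transmission_sd: 0.06
  amplitude_mean: 6.0
  amplitude_sd: 5.0
  spatial_pattern: basal
  noise_rms: 0.12
PN:
  name: PN
  insp_crackle_rate_mean: 7.0
  insp_crackle_rate_sd: 4.0
  exp_crackle_rate_mean: 5.0
  exp_crackle_rate_sd: 5.0
  pitch_mean: 284.0
  pitch_sd: 60.0
  t1_mean: 1.5
  t1_sd: 0.3
  n_half_periods_mean: 5.0
  n_half_periods_sd: 1.0
  t2_over_t1: 1.5
  amplitude_decay: 0.58
  positive_polarity_fraction: 0.70
  positive_polarity_sd: 0.19
  transmission_level: 0.23
  transmission_sd: 0.07
  amplitude_mean: 7.0
  amplitude_sd: 7.0
  spatial_pattern: focal
  noise_rms: 0.12
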