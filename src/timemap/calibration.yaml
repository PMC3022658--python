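# Default calibration of the synthetic cohort generator.
#
# A single latent schizotypy trait z ~ N(0, 1) drives the tPAS and PAS
# questionnaire responses, reaction-time slowing and the duration of the
# condition-sensitive "time-map" microstate.  The constants below were fixed
# once by large-n Monte-Carlo (scratch calibration run, n = 200_000) so that
# the generated cohorts reproduce the reference summary statistics:
#
#   corr(tPAS, PAS)                  ~ 0.57
#   tPAS score mean/SD               ~ 4.45 / 1.23   (1-10 metric)
#   PAS score mean/SD                ~ 5.9 / 4.7     (0-35 count)
#   corr(tPAS, mean RT)              ~ 0.69
#   RT condition means (ms)          475.3 / 401.1 / 480.1 (Past/Now/Future)
#   error rates                      9.2% / 6.1% / 9.8%
#   time-map durations (ms)          110.2 / 39.2 / 105.0, between-subject
#                                    SDs 12.3 / 8.4 / 15.2
#   corr(tPAS, time-map duration)    ~ 0.59
#
# Structure of the measurement models:
#   tPAS item  = round(baseline + loading * z + u_t + e_i), clipped to 1..10,
#                u_t subject-level method noise, e_i item noise
#   PAS item   ~ Bernoulli(logistic(intercept + loading * z + u_p))
#   RT trial   = (mean_c + between * u_s + slope * z) * lognormal(sigma)
#   duration   = mean_c + slope_d * z + resid_c * noise   (rounded to samples)

cohort:
  trait_mean: 0.0
  trait_sd: 1.0
  sex_ratio: 0.5
  tpas_baseline: 4.45
  tpas_loading: 1.0
  tpas_method_sd: 0.65
  tpas_item_sd: 1.3
  pas_intercept: -1.87
  pas_loading: 0.76
  pas_method_sd: 0.50

behavior:
  condition_rt_means: {Past: 475.3, Now: 401.1, Future: 480.1}
  trait_rt_slope: 110.0
  rt_sd_between: 69.5
  rt_lognormal_sigma: 0.35
  rt_floor_ms: 150.0
  # base rates sit slightly below the target group means to offset the
  # Jensen inflation from the subject-level logit noise
  error_rates: {Past: 0.0861, Now: 0.0573, Future: 0.0922}
  error_logit_sd: 0.40
  n_trials_per_condition: 240

ep:
  n_channels: 192
  sampling_rate: 2048.0
  epoch_ms: [0.0, 800.0]
  timemap_duration_means: {Past: 110.2, Now: 39.2, Future: 105.0}
  timemap_duration_resid_sd: {Past: 10.6, Now: 5.6, Future: 13.9}
  trait_duration_slope: 6.4
  noise_sd: 0.5
  envelope_floor: 1.5
  envelope_peak: 6.0
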