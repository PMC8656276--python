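# Default run configuration.
#
# Risk parameters: the <4 h and 12+ h PTSD probabilities (risk.p[0], risk.p[3])
# are the published post-9/11 dose-response endpoints (0.8% and 10.1%).  The
# middle categories risk.p[1], risk.p[2], the TV-preference fraction
# media.tv_preference_fraction, and both social-media multipliers are
# CALIBRATED values produced by `ptsdsim.risk.calibrate_params` (equivalently
# `ptsdsim calibrate`): they solve the analytic expected-prevalence equations
# against the reported baseline / scenario-2 / scenario-3 / casual / video
# prevalences (3.1 / 1.3 / 3.5 / 3.4 / 5.3 %).  Override any of them to
# explore alternative parameterizations.
population:
  size: 118000
exposure:
  n_primary_students: 900
  n_primary_adults: 30
  n_secondary_target: 4725
media:
  tv_preference_fraction: 0.3968667089390426   # calibrated
  tv_preference_by_age: null                   # optional {age_band: fraction}
  hours_weights: [0.112, 0.131, 0.108, 0.649]  # baseline <4 / 4-7 / 8-11 / 12+ h
  engagement: none                             # none | casual | video
risk:
  p: [0.008, 0.03587904259596509, 0.06450660615441486, 0.101]
  m_casual: 1.0967741935483871                 # calibrated = 0.034 / 0.031
  m_video: 1.7096774193548387                  # calibrated = 0.053 / 0.031
  cap: 1.0
calibration:
  targets:
    baseline: 0.031
    scenario1: 0.003
    scenario2: 0.013
    scenario3: 0.035
    casual: 0.034
    video: 0.053
experiment:
  replicates: 50
  scenarios: [baseline, s1_under4, s2_lower_half, s3_upper_half]
  seed: 1
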