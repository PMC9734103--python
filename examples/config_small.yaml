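# Desk-scale pipeline configuration: a reduced tweet stream (25 counties,
# 150 users per county-week) that runs end to end in well under a minute.
# The generator's statistical structure (prevalence model coefficients,
# variance components, score distributions) keeps its calibrated defaults.
generator:
  n_counties: 25
  n_states: 5
  n_weeks: 22
  users_per_county_week: 150
  min_users_per_county_week: 0
  seed: 20
threshold_policy: select
model: both
output_dir: masktrends_run
plots: false
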