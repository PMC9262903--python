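# Generative presets for the synthetic gaze cohort (version 1).
#
# Group-level targets encode the qualitative developmental pattern of gaze to
# the focus of radial flow: a contraction bias in the youngest group, an
# expansion bias from about age 5 onward, and looking times that rise with age
# up to about 5-6 years before plateauing.  Orienting latency shortens with
# age.  Numeric values are the generator's own choices (the human per-group
# means are not bundled); direction differences are kept large enough relative
# to between-participant spread (about 0.8-1.7 s at n = 20 per group) that a
# cohort's simple-effect signs are recoverable.
version: 1
latency_sigma: 0.5            # lognormal shape of the orienting latency
state_rate_per_sample: 0.05   # p_leave + p_return per 60 Hz sample (~0.33 s mixing)
jitter_sd_deg: 1.0            # fixation jitter around the AOI centre
p_invalid: 0.05               # i.i.d. per-sample tracker dropout
speed_effect_s: 0.5           # added target looking time under high speed
between_participant:
  occupancy_logit_sd: 0.35    # participant spread of in-AOI occupancy (logit scale)
  latency_log_sd: 0.15        # participant spread of latency median (log scale)
benchmark:
  latency_median_s: 0.8       # age-independent: benchmark gaze-following is mature
  latency_sigma: 0.3
  occupancy: 0.85
groups:
  "1y":  {latency_median_s: 2.0, target_looking_s: {expansion: 2.0, contraction: 3.5}}
  "2y":  {latency_median_s: 1.8, target_looking_s: {expansion: 2.6, contraction: 3.6}}
  "3y":  {latency_median_s: 1.7, target_looking_s: {expansion: 3.0, contraction: 3.8}}
  "4y":  {latency_median_s: 1.6, target_looking_s: {expansion: 4.6, contraction: 3.8}}
  "5y":  {latency_median_s: 1.5, target_looking_s: {expansion: 5.2, contraction: 4.0}}
  "6y":  {latency_median_s: 1.4, target_looking_s: {expansion: 5.6, contraction: 4.2}}
  "7y":  {latency_median_s: 1.3, target_looking_s: {expansion: 5.8, contraction: 4.4}}
  "8y":  {latency_median_s: 1.2, target_looking_s: {expansion: 5.8, contraction: 4.6}}
  "9y":  {latency_median_s: 1.2, target_looking_s: {expansion: 6.0, contraction: 4.6}}
  "10y": {latency_median_s: 1.1, target_looking_s: {expansion: 6.0, contraction: 4.7}}
  "11y": {latency_median_s: 1.1, target_looking_s: {expansion: 6.1, contraction: 4.7}}
  "12y": {latency_median_s: 1.0, target_looking_s: {expansion: 6.1, contraction: 4.8}}
  adult: {latency_median_s: 0.9, target_looking_s: {expansion: 6.2, contraction: 4.8}}
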