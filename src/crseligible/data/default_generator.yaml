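# Default synthetic-cohort configuration, calibrated to the published
# patient-characteristics table of a multicentre European CRSwNP registry
# cohort (n = 206, no prior biologic use).
#
# Median/IQR families are fitted median-anchored (see synthetic_cohort
# docstring).  Category probabilities are the printed percentages / 100 and
# are renormalized on load when they do not sum exactly to 1 (the printed
# smoking row sums to 100.1%).
#
# The nasal polyp score is published only as band frequencies with
# typographically ambiguous band labels; the 0-2 / 3-4 / 5-6 / 7-8 reading
# used here is only approximately consistent with the separately printed
# 44.3% prevalence of NPS >= 4 (uniform-within-band gives ~36%), and is the
# closest reading available.
#
# Missingness rates are 1 - (printed denominator)/206, e.g. the nasal polyp
# score was observed for 158 of 206 patients.  Fields without a printed
# denominator get rate 0.

n: 206
seed: 20210

marginals:
  age: {family: truncnorm, mean: 50.5, sd: 12.1, low: 18.0, high: 90.0, decimals: 1}
  sex: {family: categorical, labels: [male, female], probs: [0.600, 0.400]}
  bmi: {family: truncnorm, mean: 26.0, sd: 4.8, low: 14.0, high: 60.0, decimals: 1}
  smoking: {family: categorical, labels: [current, ex, never], probs: [0.133, 0.352, 0.516]}
  disease_duration: {family: lognormal, median: 11.0, q1: 4.0, q3: 21.0, high: 80.0, decimals: 1}
  n_ess:
    family: banded_int
    bands: [[0, 0], [1, 1], [2, 2], [3, 3], [4, 4]]   # ">3" stored as 4
    probs: [0.319, 0.394, 0.138, 0.085, 0.064]
  n_scs_past_year:
    family: banded_int
    bands: [[0, 0], [1, 1], [2, 2], [3, 3], [4, 4]]   # ">3" stored as 4
    probs: [0.478, 0.198, 0.154, 0.077, 0.093]
  asthma: {family: bernoulli, p: 0.597}
  allergy: {family: bernoulli, p: 0.595}
  nerd: {family: bernoulli, p: 0.240}
  snot22: {family: scaled_beta, median: 37.0, q1: 18.5, q3: 59.0, low: 0.0, high: 110.0, decimals: 0}
  lund_mackay: {family: scaled_beta, median: 14.5, q1: 9.0, q3: 20.0, low: 0.0, high: 24.0, decimals: 0}
  vas_tss: {family: scaled_beta, median: 41.0, q1: 14.5, q3: 68.5, low: 0.0, high: 100.0, decimals: 1}
  vas_nb: {family: scaled_beta, median: 33.0, q1: 8.0, q3: 65.3, low: 0.0, high: 100.0, decimals: 1}
  vas_los: {family: scaled_beta, median: 62.5, q1: 14.5, q3: 98.8, low: 0.0, high: 100.0, decimals: 1}
  nps:
    family: banded_int
    bands: [[0, 2], [3, 4], [5, 6], [7, 8]]
    probs: [0.456, 0.304, 0.215, 0.025]
  bec: {family: lognormal, median: 379.0, q1: 200.0, q3: 600.0, decimals: 1}
  ige: {family: lognormal, median: 77.0, q1: 17.0, q3: 211.5, decimals: 1}
  biologic_initiated: {family: bernoulli, p: 0.18932}   # 39/206
  incs: {family: bernoulli, p: 0.503}
  ics: {family: bernoulli, p: 0.380}

# Per-field weight on the shared standard-normal severity factor
# (Gaussian copula).  Default: all 0 = independent fields; the published
# margins alone do not identify the joint distribution.
loadings: {}

missingness:
  n_ess: 0.05340            # 1 - 195/206
  n_scs_past_year: 0.08738  # 1 - 188/206
  nps: 0.23301              # 1 - 158/206
  snot22: 0.07282           # 1 - 191/206
  vas_tss: 0.03398          # 1 - 199/206
  vas_nb: 0.04854           # 1 - 196/206
  vas_los: 0.05825          # 1 - 194/206
  bec: 0.25728              # 1 - 153/206
  ige: 0.27670              # 1 - 149/206
  asthma: 0.00971           # 1 - 204/206
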