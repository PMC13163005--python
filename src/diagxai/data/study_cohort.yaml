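# Default 17-feature synthetic cohort specification.
#
# Class-conditional marginals emulate the published per-class summaries of the
# 1000-patient ED urolithiasis cohort (stone prevalence 85.0%). Continuous
# symmetric measurements are truncated normals (mean/sd as published);
# right-skewed measurements are lognormals matched to the published median and
# IQR; binary findings are Bernoulli at the published per-class frequencies.
#
# Dipstick readings (occult blood, leukocyte esterase) are 0-4 ordinal grades.
# Only the ">=1+" aggregate frequency is published, so the split of that mass
# across grades 1-4 is a free modelling choice here (front-loaded toward 1+).
#
# Urine WBC is published as median 0 (IQR 0-1) in both classes; a lognormal fit
# to that summary is ill-posed, so it is modelled as a zero-inflated Poisson
# count (kind: continuous, dist: count_zip) — flagged here by construction.

n: 1000
prevalence: 0.85
seed: 0

features:
  age:
    family: history
    kind: continuous
    dist: normal
    stone:   {mean: 48.1, sd: 13.2}
    nostone: {mean: 44.4, sd: 16.6}
    support: [18, 95]
  sex:                      # 1 = male
    family: history
    kind: binary
    stone:   {p: 0.679}
    nostone: {p: 0.553}
  stone_history:
    family: history
    kind: binary
    stone:   {p: 0.315}
    nostone: {p: 0.127}
  pain_duration_h:
    family: history
    kind: continuous
    dist: lognormal
    stone:   {median: 2.2, q1: 1.1, q3: 5.7}
    nostone: {median: 3.8, q1: 1.0, q3: 17.1}
    support: [0.1, 240]
  pain_scale:
    family: history
    kind: continuous
    dist: normal
    stone:   {mean: 5.0, sd: 2.2}
    nostone: {mean: 4.6, sd: 2.3}
    support: [0, 10]
  nausea:
    family: physical
    kind: binary
    stone:   {p: 0.202}
    nostone: {p: 0.107}
  vomiting:
    family: physical
    kind: binary
    stone:   {p: 0.132}
    nostone: {p: 0.053}
  cva_tenderness:
    family: physical
    kind: binary
    stone:   {p: 0.608}
    nostone: {p: 0.480}
  body_temp_c:
    family: physical
    kind: continuous
    dist: normal
    stone:   {mean: 36.5, sd: 0.4}
    nostone: {mean: 36.6, sd: 0.6}
    support: [34.5, 41.0]
  le_grade:                 # leukocyte esterase dipstick grade 0-4
    family: dipstick
    kind: ordinal
    stone:   {probs: [0.892, 0.054, 0.0324, 0.0162, 0.0054]}
    nostone: {probs: [0.800, 0.100, 0.060, 0.030, 0.010]}
  specific_gravity:
    family: dipstick
    kind: continuous
    dist: normal
    stone:   {mean: 1.020, sd: 0.008}
    nostone: {mean: 1.019, sd: 0.008}
    support: [1.000, 1.050]
  occult_blood_grade:       # occult blood dipstick grade 0-4
    family: dipstick
    kind: ordinal
    stone:   {probs: [0.069, 0.326, 0.279, 0.186, 0.140]}
    nostone: {probs: [0.307, 0.243, 0.208, 0.138, 0.104]}
  urine_rbc_hpf:
    family: microscopy
    kind: continuous
    dist: lognormal
    stone:   {median: 50.0, q1: 20.0, q3: 100.0}
    nostone: {median: 20.0, q1: 1.0, q3: 100.0}
    support: [0.0, 500.0]
  urine_wbc_hpf:
    family: microscopy
    kind: continuous
    dist: count_zip
    stone:   {p_zero: 0.60, lam: 1.0}
    nostone: {p_zero: 0.55, lam: 1.0}
    support: [0.0, 200.0]
  crystalluria:
    family: microscopy
    kind: binary
    stone:   {p: 0.089}
    nostone: {p: 0.020}
  creatinine_mgdl:
    family: blood
    kind: continuous
    dist: normal
    stone:   {mean: 1.0, sd: 0.3}
    nostone: {mean: 0.9, sd: 0.3}
    support: [0.2, 8.0]
  crp_mgdl:
    family: blood
    kind: continuous
    dist: lognormal
    stone:   {median: 0.08, q1: 0.04, q3: 0.18}
    nostone: {median: 0.10, q1: 0.03, q3: 0.35}
    support: [0.01, 40.0]
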