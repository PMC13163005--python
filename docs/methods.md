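# Methods

This note records what the package actually computes, the assumptions behind
the synthetic data, the tunable parameters and their defaults, the numerical
choices made where the design was open, and what the passing tests do and do
not establish about real data.

## Synthetic cohort generator

The generator (`diagxai.cohort`) emulates a single-centre ED cohort of
patients with suspected urolithiasis undergoing non-contrast CT, with a binary
stone outcome at 85% prevalence and 17 predictors in five families
(history/demographics, physical exam, dipstick urinalysis, microscopy, blood
tests). The shipped specification (`data/study_cohort.yaml`) encodes
per-class marginals:

- **Truncated normals** for roughly symmetric measurements (age, pain scale,
  body temperature, specific gravity, creatinine). Sampling is exact
  (quantile-function of the truncated law), so the moment-recovery tests
  compare against the truncated law's theoretical moments; where truncation is
  negligible these coincide with the nominal mean/sd.
- **Lognormals matched to median and IQR** for right-skewed measurements
  (pain duration, CRP, urine RBC): log-mean = ln(median),
  log-sd = ln(q3/q1)/(2·z₀.₇₅). Values are clipped to the support (e.g. RBC
  capped at 500/HPF, mirroring how counts are reported); clipping leaves the
  median and IQR intact.
- **Zero-inflated Poisson** for urine WBC: the published summary (median 0,
  IQR 0–1 in both classes) makes a lognormal fit ill-posed, so the count is
  modelled as a point mass at zero mixed with a Poisson, flagged by
  `dist: count_zip` in the config.
- **Bernoulli** binaries at the published per-class frequencies, and **0–4
  ordinal grades** for the two dipstick readings. Only the "≥1+" aggregate is
  published, so the split of that mass across grades 1–4 is a free modelling
  choice (front-loaded toward grade 1).

Features are sampled **independently within class**: only marginals are
published, and no joint law is claimed. An optional Gaussian-copula
correlation matrix can induce dependence for sensitivity work. All sampling
routes uniforms through per-feature quantile functions, so the copula and the
independent path share one code path.

Two generating modes:

- `class_conditional` (default): outcome first (Bernoulli π), then features
  from the class-conditional laws. This is the benchmarking mode.
- `causal`: features from the pooled mixture marginals; a log-odds risk score
  is assembled from optional standardized linear terms plus **planted
  effects**, the intercept is solved (Brent) so the realized prevalence
  matches π on the drawn sample, and the outcome is Bernoulli in the resulting
  probability. Planted shapes are built from tanh steps with transition scale
  defaulting to 0.1 × the pooled SD of the feature:
  `threshold_crossing(c)` = m·tanh((x−c)/s) (log-odds effect crossing zero at
  c), `window_peak(lo,hi)` (≈ m inside the window), `negative_above(c)`
  (≈ −m above c). Recovery experiments use π = 0.5, magnitude 2.5 log-odds
  and a sharp transition: a balanced outcome maximizes information about the
  planted shape, and the recovered Shapley crossing sits where the effect
  equals its background mean, which for a sharp tanh step offsets the
  crossing from c by only ≈ s·atanh(imbalance) ≈ 0.015 mg/dL on creatinine —
  well inside the ±0.05 recovery band the tests demand.

**What the generator does not emulate:** feature correlations within class
(real dipstick blood, microscopy RBC and crystalluria co-vary), measurement
noise and digit preference, missingness (the emulated study used complete
cases), and any site- or period-specific case mix. Consequently the synthetic
cohort is *more separable* than the real one — out-of-fold AUCs land around
0.87–0.94 depending on seed versus the 0.75–0.80 range typical of real
cohorts — and microscopy RBC, whose class-conditional medians differ strongly,
dominates the importance ranking. Passing tests therefore demonstrate that the
machinery is correct and that qualitative structure (non-linear effect shapes,
stagewise gain ordering, cascade asymmetry) is recovered; they do not certify
real-data performance numbers.

## Risk models and evaluation

The boosted ensemble is scikit-learn's `GradientBoostingClassifier` with the
study hyperparameters fixed a priori (200 stages, learning rate 0.05, depth
3, min leaf 30, 80% row subsampling, √-feature selection; no grid search).
The ensemble is the instrument, not the contribution, so delegating to
scikit-learn is deliberate; every evaluation statistic is implemented in this
package:

- **Midrank AUC** (ties get half credit, the convention DeLong's variance
  assumes), verified against exhaustive pair enumeration.
- **Bootstrap AUC CI**: percentile interval over B = 1000 patient-level
  resamples stratified by outcome class — stratification avoids empty-class
  resamples at 85% prevalence.
- **DeLong's paired test** via placement values; a model compared with itself
  has exactly zero variance and p = 1 by definition. The estimator's variance
  is cross-checked against a bootstrap oracle, and its p-value against a
  10,000-rep sign-flip permutation oracle on a fixed n = 12 fixture.
- **Paired bootstrap ΔAUC** (B = 2000): percentile CI;
  p = 2·min(frac(Δ\*≤0), frac(Δ\*≥0)) clipped to [1/B, 1].
- **Held-out permutation importance**: per fold, the test-split column is
  permuted 30 times; importance is the drop in test AUC, reported mean ± sd
  across folds. A pure-noise column centres on zero (|mean ΔAUC| < 0.01 at
  n = 2000).
- **Calibration**: quantile bins (duplicate edges merged; an all-constant
  prediction vector occupies one bin), per-bin mean p vs observed rate;
  **Brier score**; **risk strata** over half-open probability intervals.

The 9-feature binary model applies predefined cutoffs (creatinine ≥ 0.92
mg/dL → 1, pain duration < 8 h → 1, dipstick occult blood ≥ 1+ → 1, RBC ≥
5/HPF → 1, plus the binary findings as-is). The exact membership of the
reference score this mirrors is not enumerated in the source material, so the
shipped list is a documented placeholder, config-driven via
`DEFAULT_BINARY_CUTOFFS`; the reference score's own point system is applied
nowhere (out of scope).

All seeds derive from one root seed through a CRC-32-labelled
`SeedSequence` rule (`diagxai.seeds.child_seed`), and every per-fold fit gets
its own derived seed, so reruns are bit-identical.

## Interventional attribution

Single-feature marginalization, exactly: φᵢⱼ = f(xᵢ) − mean over m background
rows of f(xᵢ with feature j replaced). This is *not* coalition-averaged
Shapley and *not* TreeSHAP; the reconstruction identity Σφ = f(x) − b holds
exactly only for additive f, and the mean absolute gap is reported as the
estimator's honest approximation cost (≈ 0.07–0.09 on the synthetic cohorts,
driven by the ensemble's interactions). Choices:

- background = 100 rows drawn without replacement, fixed seed; sensitivity of
  the global ranking to m ∈ {50, 100, 200} is checked and reported.
- base value b = mean background prediction, making the reconstruction
  statement checkable.
- attributions are computed for the full-cohort refit model by default (an
  out-of-fold-model option exists at the call level): explanations describe
  the deployed model, and the refit uses every patient.
- dependence-curve trend: centered rolling mean, window max(15, 5% of n),
  shrunk at the edges; zero-crossings are sign changes of the *trend* (raw φ
  is too noisy), linearly interpolated, all reported in order, and labelled
  transition regions with the window width as the uncertainty.
- a brute-force re-implementation of the same formula (independent loop) must
  agree to 1e−12; a feature the model ignores gets φ ≡ 0; |φ| ≤ 1 always
  (probability scale).

## Sequential information gain and cascade

Entropy is evaluated on q = min(p, 1−p), which makes H(p) = H(1−p) bitwise
exact, with 0·log 0 = 0 and no probability clipping. The five stage models
share hyperparameters and one stratified fold assignment; all entropy
accounting uses held-out probabilities. Two parallel accounts are kept,
deliberately:

- **population mean entropy per stage over all patients** (this is what the
  marginal/cumulative gain percentages are computed from; marginal gains
  telescope exactly to the cumulative gain), and
- **the resolution cascade** (first stage with p > τ_high or p < τ_low,
  strictly; resolved patients keep their classification), whose per-stage
  rule-in/low counts and final three-group partition are reported separately.

The emulated study reports both accountings with totals that do not fully
reconcile (its stage-wise threshold counts and its final-partition figure
differ, as do its prose and table marginal-gain values); this package
computes both from one definition each and labels them, rather than trying to
reproduce two inconsistent tallies with one number.

Thresholds default to 0.90/0.20 with an 0.85/0.30 alternate. At 85%
prevalence the low arm is structurally weak — even p < 0.20 corresponds to a
non-trivial stone rate — which is exactly what the prevalence projection
quantifies.

## Prevalence projection

Operating points use p ≥ τ_high (test positive) and p ≤ τ_low (test
negative): the boundary is *included* here, unlike the cascade's strict
inequalities, matching the "probability ≤ 0.20" phrasing of the predictive-
value analysis being emulated; both conventions are surfaced in config.
PPV/NPV at any prevalence follow from the likelihood ratios; the projection
at the source prevalence reproduces the empirical 2×2 predictive values
exactly, and the odds form agrees with the direct formula to 1e−12. Published
projected values are checked as likelihood-ratio arithmetic from the
published anchors (PPV 94.1% / NPV 86.7% at π = 0.85), with the ≈0.2
percentage-point slack that back-solving through 1-d.p. anchors propagates.

## Problem sizes used by the test suite and acceptance script

Chosen as the package's own defaults: benchmarking cohorts of n = 1000 (the
emulated study's size), moment-recovery checks at n = 50,000, causal recovery
at n = 4000 × 20 seeds (tests) or 5 seeds (acceptance script), bootstrap
coverage over 500 binormal cohorts of n = 200 at B = 1000, and pipeline
determinism on n = 1000 with reduced replicate counts (200 bootstrap / 200
paired resamples / 5 permutation repeats) — determinism is invariant to
replicate counts, while the statistical defaults remain B = 1000 / 2000 / 30.

## Known limitations

- Class-conditional independence makes the synthetic cohort optimistic; none
  of the absolute discrimination numbers transfer to real data.
- The interventional estimator attributes through off-manifold evaluation
  points when features are correlated; on the independent synthetic cohorts
  this cost is invisible by construction.
- Zero-crossing locations inherit rolling-window smoothing bias of order the
  window's feature-value span; they are transition regions, not cut-points.
- The cascade uses out-of-fold probabilities (the only fold-pure per-patient
  values available); a deployed model would emit refit probabilities, and the
  cascade fractions would shift accordingly.
- Stage gains are total entropy reductions per stage, including any
  re-weighting of earlier features the expanded feature set induces; a
  decomposition separating direct from interaction contributions would need
  conditional attributions and is out of scope.
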