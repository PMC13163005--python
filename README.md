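# diagxai

Explainable machine-learning diagnostics for suspected urolithiasis in the
emergency department: a gradient-boosted risk model with strictly out-of-fold
evaluation, interventional Shapley-style feature attributions, a Shannon-entropy
account of how much diagnostic uncertainty each sequential testing stage
resolves, and a Bayes projection of threshold operating points across baseline
prevalences.

## The problem

ED patients with acute flank pain are usually triaged to non-contrast CT, yet
not all of them need imaging. Classical clinical prediction rules dichotomize
continuous measurements (creatinine ≥ 0.92 mg/dL, pain < 8 h, …), which makes
them portable but discards information and says nothing about *why* a given
patient is at risk or *how much* uncertainty remains after each test. This
package implements, as tested reusable code, a framework that answers those
questions:

- **Risk model.** A gradient-boosted tree ensemble (200 stages, learning rate
  0.05, depth 3, minimum leaf 30, 80% subsampling, √-feature selection) over 17
  routinely collected features — five history/demographic, four physical-exam,
  three dipstick, three microscopy, two blood — with 9-feature binary/continuous
  counterparts and a standardized logistic baseline. All per-patient
  probabilities come from five-fold stratified cross-validation held-out folds;
  discrimination is midrank AUC with class-stratified bootstrap CIs, calibration
  is quantile-binned with the Brier score, and model comparisons use DeLong's
  paired test and a patient-level paired bootstrap.
- **Attribution.** For patient *i* and feature *j*,
  φᵢⱼ = f(xᵢ) − (1/m) Σᵣ f(xᵢ with xᵢⱼ ← x_{rj}) over a background sample of
  m = 100 cohort rows — the interventional (marginalization) estimator on the
  probability scale, deliberately not exact coalition TreeSHAP. The base value
  b is the mean background prediction; Σⱼ φᵢⱼ − (f(xᵢ) − b) is the reported
  reconstruction error. Dependence curves with centered rolling-mean trends
  locate zero-crossings ("transition regions") of each feature's effect.
- **Information gain.** Diagnostic uncertainty is the binary entropy
  H(p) = −p log₂ p − (1−p) log₂(1−p) in bits, anchored at the prevalence prior
  H₀ = H(π). Five nested stage models (history → +physical → +dipstick →
  +microscopy → +blood) share one fold assignment; the marginal gain of stage s
  is 100·(H̄ₛ₋₁ − H̄ₛ)/H₀, and a resolution cascade lets a patient exit at the
  first stage with p > τ_high (= 0.90) or p < τ_low (= 0.20).
- **Prevalence projection.** Each threshold's empirical (Se, Sp) gives
  LR⁺ = Se/(1−Sp) and LR⁻ = (1−Se)/Sp; posterior odds = LR × prior odds turn
  into PPV/NPV at any baseline prevalence.

Because the patient-level cohort behind the framework is not public, the
package ships a seeded synthetic cohort generator that emulates the published
class-conditional feature summaries (prevalence 85%, truncated normals,
median/IQR-matched lognormals, Bernoulli and ordinal-grade features) and can
*plant* known non-linear effects — a log-odds threshold crossing, a window
peak, a negative step — so the explainability machinery can be tested against
a known ground truth.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 7      # results/cohort.csv
python analysis/02_fit_models.py      --seed 7
python analysis/03_explain.py         --seed 7
python analysis/04_entropy_cascade.py --seed 7
python analysis/05_prevalence_projection.py --seed 7
```

On the seed-7 synthetic cohort (n = 1000, realized prevalence 0.838) this
prints, among other tables:

```
gbm-17     AUC 0.938 [0.915, 0.957]  Brier 0.060
gbm-9bin   AUC 0.867 [0.835, 0.899]  Brier 0.079
DeLong 17-feature vs 9-binary: delta AUC +0.071, p = 0.0000

creatinine_mgdl: trend zero-crossings at [0.902] (window 50 patients)

cascade at 0.90/0.20: resolved 91.4% (rule-in 847, low 67,
  unresolved 86 with stone prevalence 67.4%)

at the cohort prevalence (0.84): PPV 97.6%, NPV 92.6%
projected to prevalence 0.40: PPV 84.2%, NPV 99.0%
```

Reading this: the 17-feature model outperforms its dichotomized counterpart
(the gap is what binarization throws away); the creatinine contribution
changes sign near 0.90 mg/dL — below the conventional 0.92 cutoff — emerging
from the class-conditional marginals alone; most patients resolve through the
high-probability arm, the unresolved remainder sits at an intermediate stone
rate, and the rule-in threshold loses much of its predictive value when
projected to an unselected-population prevalence. The synthetic cohort is
deliberately simpler than real data (features independent within class), so
absolute AUCs run higher than a real cohort would give; the qualitative
structure, not the headline AUC, is the point.

The same steps are available as a CLI (`diagxai synth | fit-eval | explain |
cascade | project | run`), and `diagxai run` executes the whole pipeline from
one config into a directory of CSV/JSON tables with a seed manifest.

## Layout

```
src/diagxai/        library: cohort, models, shapley, entropy, projection,
                    pipeline, cli (+ data/study_cohort.yaml, the shipped
                    class-conditional cohort specification)
analysis/           numbered narrative drivers for the five analysis steps
tests/              pytest suite, including tests/test_acceptance.py
scripts/acceptance.py
docs/methods.md     modelling assumptions, parameter choices, limitations
```
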