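#!/usr/bin/env python
"""Prevalence projection of the threshold operating points.

Estimates the 0.90 (rule-in) and 0.20 (low-probability) operating points from
the final-stage held-out predictions, then projects PPV/NPV across baseline
prevalences 0.05-0.95 via the likelihood ratios. The message the projection
carries: the high-probability threshold loses most of its positive predictive
value in unselected-population prevalence ranges (30-50%), while the
low-probability threshold only becomes a credible rule-out there.
Writes results/projection/projection_grid.csv.
"""

import argparse
from pathlib import Path

import numpy as np

import diagxai as d
from diagxai.seeds import child_seed


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/projection"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohort = d.read_cohort(args.cohort)
    y = cohort["outcome"].to_numpy(dtype=int)
    folds = d.stratified_folds(y, k=5, seed=child_seed(args.seed, "folds"))
    config = d.ModelConfig(seed=child_seed(args.seed, "model"))
    features = [c for c in cohort.columns if c not in ("patient_id", "outcome")]
    preds = d.oof_predict(cohort, features, config, folds)

    op_hi = d.operating_point(preds, tau=0.90, arm="high")
    op_lo = d.operating_point(preds, tau=0.20, arm="low")
    print(f"high arm (p >= 0.90): Se {op_hi.sensitivity:.3f}, Sp {op_hi.specificity:.3f}, "
          f"LR+ {op_hi.lr_pos:.2f}")
    print(f"low arm  (p <= 0.20): Se {op_lo.sensitivity:.3f}, Sp {op_lo.specificity:.3f}, "
          f"LR- {op_lo.lr_neg:.3f}")

    pi = float(y.mean())
    ppv, _ = d.project_ppv_npv(op_hi, pi)
    _, npv = d.project_ppv_npv(op_lo, pi)
    print(f"\nat the cohort prevalence ({pi:.2f}): PPV {100 * ppv:.1f}%, NPV {100 * npv:.1f}%")

    grid = d.projection_table(op_hi, op_lo, np.round(np.arange(0.05, 0.951, 0.05), 2))
    grid.to_csv(args.out / "projection_grid.csv", index=False)
    for target in (0.40, 0.30):
        row = grid[np.isclose(grid["prevalence"], target)].iloc[0]
        print(f"projected to prevalence {target:.2f}: "
              f"PPV {100 * row['ppv_high']:.1f}%, NPV {100 * row['npv_low']:.1f}%")


if __name__ == "__main__":
    main()
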