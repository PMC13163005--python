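#!/usr/bin/env python
"""Simulate the study cohort.

Generates the default 17-feature synthetic cohort (n=1000, stone prevalence
85%) from the shipped class-conditional specification, writes it to
results/cohort.csv, and prints a per-class summary so the emulated marginals
can be eyeballed against the published baseline table.
"""

import argparse
from pathlib import Path

import diagxai as d


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--n", type=int, default=1000)
    ap.add_argument("--out", type=Path, default=Path("results/cohort.csv"))
    args = ap.parse_args()

    spec = d.default_cohort_spec(n=args.n, seed=args.seed, prevalence=0.85)
    cohort = d.generate_cohort(spec, mode="class_conditional")
    args.out.parent.mkdir(parents=True, exist_ok=True)
    d.write_cohort(cohort, args.out)

    y = cohort["outcome"]
    print(f"cohort: n={len(cohort)}, prevalence={y.mean():.3f} -> {args.out}")
    print("\nper-class means (stone vs no stone):")
    grouped = cohort.drop(columns=["patient_id"]).groupby("outcome").mean().T
    grouped.columns = ["no_stone", "stone"]
    print(grouped[["stone", "no_stone"]].round(3).to_string())


if __name__ == "__main__":
    main()
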