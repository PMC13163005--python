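"""End-to-end pipeline: cohort -> models -> explanations -> entropy cascade ->
prevalence projection, with every seed derived from one root seed and every
output written as CSV/JSON so that two runs with the same config are
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortSpec, default_cohort_spec, generate_cohort, read_cohort, write_cohort
from .entropy import (ResolutionThresholds, cascade_summary, default_stages,
                      fit_stage_models, prior_entropy, sequential_resolution,
                      stage_entropy_summary, trajectories_by_outcome)
from .models import (DEFAULT_BINARY_CUTOFFS, ModelConfig, binarize_features,
                     bootstrap_auc_ci, brier_score, calibration_table,
                     delong_test, fit_logistic_baseline, fit_tree_ensemble,
                     oof_predict, paired_bootstrap_delta_auc,
                     permutation_importance_heldout, risk_strata_table, roc_auc,
                     stratified_folds)
from .projection import operating_point, projection_table
from .seeds import child_seed
from .shapley import (dependence_curve, interventional_contributions,
                      reconstruction_error, sample_background,
                      stratified_contribution_table, waterfall)

__all__ = ["RunConfig", "run_pipeline"]

_NINE_CONTINUOUS = [
    "sex", "stone_history", "pain_duration_h", "nausea", "vomiting",
    "cva_tenderness", "occult_blood_grade", "urine_rbc_hpf", "creatinine_mgdl",
]


@dataclass
class RunConfig:
    """Everything one pipeline run needs, seeded from a single root seed."""

    seed: int = 0
    n: int = 1000
    prevalence: float = 0.85
    cohort_path: str | None = None      # load instead of generating
    model: ModelConfig | None = None
    k_folds: int = 5
    bootstrap_B: int = 1000
    paired_B: int = 2000
    perm_repeats: int = 30
    background_m: int = 100
    thresholds: ResolutionThresholds = dc_field(default_factory=ResolutionThresholds)
    alt_thresholds: ResolutionThresholds = dc_field(
        default_factory=lambda: ResolutionThresholds(0.85, 0.30))
    projection_grid: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))
    out_dir: str = "results/run"

    def __post_init__(self):
        if self.model is None:
            self.model = ModelConfig(seed=child_seed(self.seed, "model"))
        for name in ("bootstrap_B", "paired_B", "perm_repeats", "background_m"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("seed", "n", "prevalence", "cohort_path", "k_folds", "bootstrap_B",
                    "paired_B", "perm_repeats", "background_m", "out_dir"):
            if key in cfg:
                kwargs[key] = cfg[key]
        if "thresholds" in cfg:
            kwargs["thresholds"] = ResolutionThresholds(*cfg["thresholds"])
        if "alt_thresholds" in cfg:
            kwargs["alt_thresholds"] = ResolutionThresholds(*cfg["alt_thresholds"])
        rc = cls(**kwargs)
        if "model" in cfg:
            rc.model = ModelConfig(seed=child_seed(rc.seed, "model"), **cfg["model"])
        return rc


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _model_report(name, preds, config: RunConfig) -> dict:
    lo, hi = bootstrap_auc_ci(preds, B=config.bootstrap_B,
                              seed=child_seed(config.seed, "bootstrap", name))
    return {
        "model": name,
        "auc": roc_auc(preds),
        "auc_ci": [lo, hi],
        "brier": brier_score(preds),
    }


def _select_archetypes(attr, cohort) -> dict[str, int]:
    """Rule-based counterparts of the four illustrative cases:
    max-p correct, min-p correct, most-conflicted, max-p incorrect."""
    y = cohort["outcome"].to_numpy(dtype=int)
    pid = cohort["patient_id"].to_numpy()
    p = attr.prediction
    abs_sum = attr.phi.abs().sum(axis=1).to_numpy()
    net = np.abs(attr.phi.sum(axis=1).to_numpy())
    cases = {}
    pos, neg = y == 1, y == 0
    cases["A_classic_stone"] = int(pid[pos][np.argmax(p[pos])]) if pos.any() else None
    cases["B_correct_low"] = int(pid[neg][np.argmin(p[neg])]) if neg.any() else None
    conflicted = net <= np.median(net)
    cases["C_conflicted"] = int(pid[conflicted][np.argmax(abs_sum[conflicted])])
    cases["D_mimicker"] = int(pid[neg][np.argmax(p[neg])]) if neg.any() else None
    return cases


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis; returns a dict of key results and writes all
    tables under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "root_seed": config.seed,
        "seeds": {},
        "stages_completed": [],
    }

    # --- cohort ----------------------------------------------------------
    if config.cohort_path:
        cohort = read_cohort(config.cohort_path)
    else:
        spec = default_cohort_spec(n=config.n, prevalence=config.prevalence,
                                   seed=child_seed(config.seed, "cohort"))
        manifest["seeds"]["cohort"] = spec.seed
        cohort = generate_cohort(spec, mode="class_conditional")
    write_cohort(cohort, out / "cohort.csv")
    features17 = [c for c in cohort.columns if c not in ("patient_id", "outcome")]
    y = cohort["outcome"].to_numpy(dtype=int)
    manifest["stages_completed"].append("cohort")

    # --- models ----------------------------------------------------------
    fold_seed = child_seed(config.seed, "folds")
    manifest["seeds"]["folds"] = fold_seed
    folds = stratified_folds(y, k=config.k_folds, seed=fold_seed)
    manifest["seeds"]["model"] = config.model.seed

    preds17 = oof_predict(cohort, features17, config.model, folds, tag="gbm-17")
    preds9c = oof_predict(cohort, _NINE_CONTINUOUS, config.model, folds, tag="gbm-9cont")
    cohort_bin = binarize_features(cohort, DEFAULT_BINARY_CUTOFFS)
    preds9b = oof_predict(cohort_bin, list(DEFAULT_BINARY_CUTOFFS), config.model, folds, tag="gbm-9bin")
    preds_lr = oof_predict(cohort, features17, config.model, folds, model="logistic", tag="logistic-17")

    reports = [_model_report(p.tag, p, config)
               for p in (preds17, preds9c, preds9b, preds_lr)]
    d_delta, d_z, d_p = delong_test(preds17, preds9b)
    pb_delta, pb_ci, pb_p = paired_bootstrap_delta_auc(
        preds17, preds_lr, B=config.paired_B,
        seed=child_seed(config.seed, "paired-bootstrap"))
    comparison = {
        "delong_17_vs_9bin": {"delta_auc": d_delta, "z": d_z, "p": d_p},
        "paired_bootstrap_17_vs_logistic": {
            "mean_delta_auc": pb_delta, "ci": list(pb_ci), "p": pb_p},
    }
    _write_json(out / "model_reports.json", {"models": reports, "comparisons": comparison})
    calibration_table(preds17).to_csv(out / "calibration_gbm17.csv", index=False)
    risk_strata_table(preds17).to_csv(out / "risk_strata_gbm17.csv", index=False)
    importance = permutation_importance_heldout(
        cohort, features17, config.model, folds, repeats=config.perm_repeats,
        seed=child_seed(config.seed, "importance"))
    importance.to_csv(out / "permutation_importance.csv", index=False)
    manifest["stages_completed"].append("models")

    # --- explainability --------------------------------------------------
    full_model = fit_tree_ensemble(cohort, features17, config.model)
    bg_seed = child_seed(config.seed, "background")
    manifest["seeds"]["background"] = bg_seed
    background = sample_background(cohort, m=config.background_m, seed=bg_seed)
    attr = interventional_contributions(full_model, cohort, background)
    attr_out = attr.phi.copy()
    attr_out.insert(0, "patient_id", cohort["patient_id"].to_numpy())
    attr_out["base_value"] = attr.base_value
    attr_out["prediction"] = attr.prediction
    attr_out.to_csv(out / "attributions.csv", index=False)
    attr.mean_abs().rename("mean_abs_phi").to_csv(out / "global_importance.csv")
    _, mean_gap = reconstruction_error(attr)

    strata_tables = {}
    for feat, edges in (
        ("creatinine_mgdl", [0.0, 0.70, 0.87, 0.92, 1.20, 8.0]),
        ("pain_duration_h", [0.0, 1.0, 2.0, 5.0, 16.0, 240.0]),
        ("crp_mgdl", [0.0, 0.5, 3.0, 40.0]),
    ):
        if feat in cohort.columns:
            tab = stratified_contribution_table(attr, cohort, feat, edges)
            tab.to_csv(out / f"strata_{feat}.csv", index=False)
            strata_tables[feat] = tab

    crossings = {}
    for feat in ("creatinine_mgdl", "pain_duration_h", "crp_mgdl"):
        if feat in cohort.columns and np.ptp(cohort[feat].to_numpy()) > 0:
            curve = dependence_curve(attr, cohort, feat)
            crossings[feat] = {
                "zero_crossings": curve.zero_crossings,
                "window": curve.window,
                "note": "transition region; width of the rolling window is the uncertainty",
            }
    _write_json(out / "dependence_crossings.json", crossings)

    archetypes = _select_archetypes(attr, cohort)
    waterfalls = {}
    for label, pid in archetypes.items():
        if pid is None:
            continue
        wf = waterfall(attr, pid, cohort)
        waterfalls[label] = {
            "patient_id": wf.patient_id,
            "base_value": wf.base_value,
            "prediction": wf.prediction,
            "reconstructed": wf.reconstructed,
            "entries": [{"feature": f, "value": v, "phi": c} for f, v, c in wf.entries],
            "other": wf.other,
        }
    _write_json(out / "waterfalls.json", waterfalls)
    _write_json(out / "explain_summary.json", {
        "base_value": attr.base_value,
        "mean_abs_reconstruction_error": mean_gap,
        "archetypes": archetypes,
    })
    manifest["stages_completed"].append("explain")

    # --- entropy cascade -------------------------------------------------
    stages = default_stages()
    pi, h0 = prior_entropy(y)
    stage_preds = fit_stage_models(cohort, stages, config.model, folds)
    stage_report = stage_entropy_summary(stage_preds, h0, stages=stages,
                                         thresholds=config.thresholds)
    stage_report.to_csv(out / "stage_report.csv", index=False)
    trajectories_by_outcome(stage_preds).to_csv(out / "entropy_trajectories.csv", index=False)

    cascade_results = {}
    for label, thr in (("default", config.thresholds), ("alternate", config.alt_thresholds)):
        cascade = sequential_resolution(stage_preds, thr)
        summary = cascade_summary(cascade, y)
        cascade_results[label] = {
            "tau_high": thr.tau_high, "tau_low": thr.tau_low,
            "cumulative_resolved_frac": cascade.cumulative_resolved_frac.tolist(),
            "unresolved_frac": cascade.unresolved_frac,
            "unresolved_prevalence": cascade.unresolved_prevalence,
            "partition": summary,
        }
        per_patient = pd.DataFrame({
            "patient_id": cohort["patient_id"],
            "resolution_stage": cascade.resolution_stage,
            "arm": cascade.arm,
            "final_class": cascade.final_class,
        })
        per_patient.to_csv(out / f"cascade_{label}.csv", index=False)
    _write_json(out / "cascade_summary.json",
                {"prior": {"prevalence": pi, "h0_bits": h0}, **cascade_results})
    manifest["stages_completed"].append("entropy")

    # --- prevalence projection -------------------------------------------
    final_preds = stage_preds[-1]
    op_high = operating_point(final_preds, tau=config.thresholds.tau_high, arm="high")
    op_low = operating_point(final_preds, tau=config.thresholds.tau_low, arm="low")
    grid = projection_table(op_high, op_low, config.projection_grid)
    grid.to_csv(out / "projection_grid.csv", index=False)
    _write_json(out / "operating_points.json", {
        "high": {"tau": op_high.threshold, "se": op_high.sensitivity,
                 "sp": op_high.specificity, "tp": op_high.tp, "fp": op_high.fp,
                 "fn": op_high.fn, "tn": op_high.tn},
        "low": {"tau": op_low.threshold, "se": op_low.sensitivity,
                "sp": op_low.specificity, "tp": op_low.tp, "fp": op_low.fp,
                "fn": op_low.fn, "tn": op_low.tn},
    })
    manifest["stages_completed"].append("projection")

    _write_json(out / "manifest.json", manifest)
    return {
        "cohort": cohort,
        "folds": folds,
        "preds": {"gbm17": preds17, "gbm9cont": preds9c, "gbm9bin": preds9b,
                  "logistic": preds_lr},
        "reports": reports,
        "comparisons": comparison,
        "importance": importance,
        "attr": attr,
        "reconstruction_error": mean_gap,
        "crossings": crossings,
        "stage_preds": stage_preds,
        "stage_report": stage_report,
        "cascade": cascade_results,
        "projection": grid,
        "manifest": manifest,
    }
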