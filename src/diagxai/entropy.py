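"""Shannon-entropy sequential information-gain framework.

Diagnostic uncertainty for a predicted stone probability p is the binary
entropy H(p) = -p log2 p - (1-p) log2(1-p), in bits, maximal (1 bit) at
p = 0.5 and zero at certainty. The prior entropy H0 is the entropy of the
cohort prevalence — what a clinician knows before any testing.

Five nested testing stages mirror the ED workflow (history/demographics,
+physical exam, +dipstick urinalysis, +microscopy, +blood tests). A separate
model is trained per stage on the cumulative feature set, under one shared
stratified fold assignment, and all entropy accounting uses the held-out
probabilities. The marginal gain of stage s is 100*(H_{s-1}-H_s)/H0 with
H_0 the prior; marginal gains telescope exactly to the cumulative gain.
Population mean entropy at each stage is computed over all patients, while
the resolution cascade is a parallel account: a patient exits at the first
stage whose probability strictly exceeds tau_high (rule-in) or falls strictly
below tau_low (low-probability), and keeps that classification thereafter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, PairingError
from .models import FoldAssignment, ModelConfig, OofPredictions, oof_predict, roc_auc
from .seeds import child_seed

__all__ = [
    "StageDefinition",
    "ResolutionThresholds",
    "CascadeResult",
    "default_stages",
    "binary_entropy",
    "prior_entropy",
    "fit_stage_models",
    "stage_gains",
    "stage_entropy_summary",
    "trajectories_by_outcome",
    "sequential_resolution",
    "cascade_summary",
]


@dataclass(frozen=True)
class StageDefinition:
    index: int                  # 1-based
    label: str
    features: tuple[str, ...]   # cumulative feature list


@dataclass(frozen=True)
class ResolutionThresholds:
    tau_high: float = 0.90
    tau_low: float = 0.20

    def __post_init__(self):
        if not 0.0 < self.tau_low < self.tau_high < 1.0:
            raise ValueError(
                f"thresholds must satisfy 0 < tau_low < tau_high < 1, got ({self.tau_low}, {self.tau_high})")


@dataclass
class CascadeResult:
    """Per-patient resolution bookkeeping plus population accounting."""

    resolution_stage: np.ndarray    # 1..S, or 0 = unresolved
    arm: np.ndarray                 # 'high' | 'low' | 'none'
    final_class: np.ndarray         # 1 rule-in, 0 rule-out, -1 unresolved
    cumulative_resolved_frac: np.ndarray   # per stage
    unresolved_frac: float
    unresolved_prevalence: float
    thresholds: ResolutionThresholds


_STAGE_FEATURES = (
    ("Stage 1: History", ("age", "sex", "stone_history", "pain_duration_h", "pain_scale")),
    ("Stage 2: +Physical", ("nausea", "vomiting", "cva_tenderness", "body_temp_c")),
    ("Stage 3: +Dipstick", ("le_grade", "specific_gravity", "occult_blood_grade")),
    ("Stage 4: +Microscopy", ("urine_rbc_hpf", "urine_wbc_hpf", "crystalluria")),
    ("Stage 5: +Blood", ("creatinine_mgdl", "crp_mgdl")),
)


def default_stages() -> list[StageDefinition]:
    """The five cumulative ED workflow stages (5, 9, 12, 15, 17 features)."""
    stages = []
    cumulative: tuple[str, ...] = ()
    for i, (label, added) in enumerate(_STAGE_FEATURES, start=1):
        cumulative = cumulative + added
        stages.append(StageDefinition(index=i, label=label, features=cumulative))
    return stages


def binary_entropy(p) -> np.ndarray | float:
    """H(p) in bits, elementwise; 0*log2(0) taken as 0."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise DomainError(f"probabilities must lie in [0, 1], got {arr[(arr < 0) | (arr > 1) | np.isnan(arr)][:5]}")
    # evaluate on q = min(p, 1-p): bitwise-identical H(p) and H(1-p)
    q = np.minimum(arr, 1.0 - arr)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -q * np.log2(q) - (1.0 - q) * np.log2(1.0 - q)
    h = np.where(q == 0, 0.0, h)
    return float(h) if np.isscalar(p) or np.ndim(p) == 0 else h


def prior_entropy(outcomes) -> tuple[float, float]:
    """(prevalence, H0) from observed outcomes."""
    y = np.asarray(outcomes, dtype=float)
    pi = float(y.mean())
    return pi, float(binary_entropy(pi))


def fit_stage_models(cohort: pd.DataFrame, stages: list[StageDefinition],
                     config: ModelConfig, folds: FoldAssignment,
                     model: str = "gbm") -> list[OofPredictions]:
    """One OOF prediction set per stage, all sharing the same fold assignment
    and the same hyperparameters (only the feature subset differs)."""
    out = []
    for stage in stages:
        preds = oof_predict(cohort, list(stage.features), config, folds,
                            model=model, tag=f"stage{stage.index}")
        out.append(preds)
    return out


def _check_aligned(stage_preds: list[OofPredictions]) -> np.ndarray:
    y = stage_preds[0].y
    for sp in stage_preds[1:]:
        if len(sp) != len(y) or not np.array_equal(sp.y, y):
            raise PairingError("stage predictions cover inconsistent patient sets")
    return y


def stage_gains(mean_h: list[float], h0: float) -> tuple[list[float], list[float]]:
    """Marginal and cumulative entropy reductions as % of the prior entropy.

    ``mean_h[s]`` is the mean population entropy after stage s+1; the marginal
    gain of stage 1 is taken against H0. Marginal values telescope exactly to
    the cumulative values (pre-rounding).
    """
    marginal, cumulative = [], []
    prev = h0
    for h in mean_h:
        marginal.append(100.0 * (prev - h) / h0)
        cumulative.append(100.0 * (h0 - h) / h0)
        prev = h
    return marginal, cumulative


def stage_entropy_summary(stage_preds: list[OofPredictions], h0: float,
                          stages: list[StageDefinition] | None = None,
                          thresholds: ResolutionThresholds | None = None) -> pd.DataFrame:
    """Per-stage report: AUC, mean entropy, marginal/cumulative gains, and
    cumulative cascade resolution counts with their observed stone rates."""
    y = _check_aligned(stage_preds)
    thresholds = thresholds or ResolutionThresholds()
    mean_h = [float(np.mean(binary_entropy(sp.p))) for sp in stage_preds]
    marginal, cumulative = stage_gains(mean_h, h0)
    cascade = sequential_resolution(stage_preds, thresholds, outcomes=y)
    rows = []
    for s, sp in enumerate(stage_preds, start=1):
        resolved_high = (cascade.arm == "high") & (cascade.resolution_stage <= s) & (cascade.resolution_stage > 0)
        resolved_low = (cascade.arm == "low") & (cascade.resolution_stage <= s) & (cascade.resolution_stage > 0)
        rows.append({
            "stage": s,
            "label": stages[s - 1].label if stages else f"stage {s}",
            "n_features": len(stages[s - 1].features) if stages else np.nan,
            "auc": roc_auc(sp),
            "mean_h_bits": mean_h[s - 1],
            "marginal_gain_pct": marginal[s - 1],
            "cumulative_gain_pct": cumulative[s - 1],
            "rule_in_n": int(resolved_high.sum()),
            "rule_in_stone_pct": float(100.0 * y[resolved_high].mean()) if resolved_high.any() else np.nan,
            "low_prob_n": int(resolved_low.sum()),
            "low_prob_stone_pct": float(100.0 * y[resolved_low].mean()) if resolved_low.any() else np.nan,
        })
    return pd.DataFrame(rows)


def trajectories_by_outcome(stage_preds: list[OofPredictions]) -> pd.DataFrame:
    """Mean entropy per stage, separately for stone and non-stone patients."""
    y = _check_aligned(stage_preds)
    rows = []
    for s, sp in enumerate(stage_preds, start=1):
        h = binary_entropy(sp.p)
        rows.append({
            "stage": s,
            "mean_h_stone": float(h[y == 1].mean()),
            "mean_h_nostone": float(h[y == 0].mean()),
        })
    return pd.DataFrame(rows)


def sequential_resolution(stage_preds: list[OofPredictions] | np.ndarray,
                          thresholds: ResolutionThresholds,
                          outcomes=None) -> CascadeResult:
    """Scan stages 1..S; each patient exits at the first stage with
    p > tau_high (high arm) or p < tau_low (low arm), strictly.

    ``stage_preds`` may be OofPredictions (outcomes taken from them) or a raw
    (n, S) probability matrix with ``outcomes`` supplied separately.
    """
    if isinstance(stage_preds, np.ndarray):
        P = np.asarray(stage_preds, dtype=float)
        y = np.asarray(outcomes, dtype=int) if outcomes is not None else None
    else:
        y = _check_aligned(stage_preds)
        P = np.column_stack([sp.p for sp in stage_preds])
    n, S = P.shape
    stage = np.zeros(n, dtype=int)
    arm = np.full(n, "none", dtype=object)
    cum_frac = np.zeros(S)
    unresolved = np.ones(n, dtype=bool)
    for s in range(S):
        hi = unresolved & (P[:, s] > thresholds.tau_high)
        lo = unresolved & (P[:, s] < thresholds.tau_low)
        stage[hi] = s + 1
        stage[lo] = s + 1
        arm[hi] = "high"
        arm[lo] = "low"
        unresolved &= ~(hi | lo)
        resolved_n = n - int(unresolved.sum())
        assert resolved_n + int(unresolved.sum()) == n  # conservation at every stage
        cum_frac[s] = resolved_n / n
    final_class = np.where(arm == "high", 1, np.where(arm == "low", 0, -1))
    unresolved_prev = float(np.mean(np.asarray(y)[unresolved])) if (y is not None and unresolved.any()) else np.nan
    return CascadeResult(
        resolution_stage=stage, arm=arm.astype(str), final_class=final_class,
        cumulative_resolved_frac=cum_frac,
        unresolved_frac=float(unresolved.mean()),
        unresolved_prevalence=unresolved_prev,
        thresholds=thresholds)


def cascade_summary(cascade: CascadeResult, outcomes) -> dict:
    """Final three-group partition (rule-in / low-probability / unresolved)
    with counts and observed stone prevalences."""
    y = np.asarray(outcomes, dtype=int)
    out = {}
    for label, mask in (
        ("rule_in", cascade.final_class == 1),
        ("low_probability", cascade.final_class == 0),
        ("unresolved", cascade.final_class == -1),
    ):
        out[label] = {
            "n": int(mask.sum()),
            "fraction": float(mask.mean()),
            "stone_prevalence": float(y[mask].mean()) if mask.any() else np.nan,
        }
    assert sum(g["n"] for g in out.values()) == len(y)
    return out
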