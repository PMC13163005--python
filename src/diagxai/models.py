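"""Risk-model fitting and out-of-fold evaluation machinery.

The predictive instrument is a gradient-boosted tree ensemble (scikit-learn's
``GradientBoostingClassifier`` with the study hyperparameters: 200 stages,
learning rate 0.05, depth 3, minimum leaf 30, 80% row subsampling, square-root
feature selection per split), evaluated by five-fold stratified cross-validation
with all per-patient probabilities taken from held-out folds.

Every evaluation statistic is implemented here directly:

- midrank (tie-aware) Mann-Whitney AUC,
- class-stratified percentile bootstrap CI for a single AUC,
- Brier score and quantile-binned calibration tables,
- DeLong's paired test for correlated AUCs (placement-value covariances),
- paired patient-level bootstrap for an AUC difference,
- held-out permutation feature importance (delta AUC on permuted test columns),
- predefined-cutoff dichotomization and predicted-probability risk strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .errors import FitError, PairingError, StratificationError
from .seeds import child_seed

__all__ = [
    "ModelConfig",
    "FoldAssignment",
    "OofPredictions",
    "Predictor",
    "stratified_folds",
    "fit_tree_ensemble",
    "fit_logistic_baseline",
    "oof_predict",
    "roc_auc",
    "bootstrap_auc_ci",
    "brier_score",
    "calibration_table",
    "delong_test",
    "delong_auc_variance",
    "paired_bootstrap_delta_auc",
    "permutation_importance_heldout",
    "binarize_features",
    "risk_strata_table",
    "DEFAULT_BINARY_CUTOFFS",
]


@dataclass(frozen=True)
class ModelConfig:
    """Gradient-boosting hyperparameters (study defaults)."""

    n_trees: int = 200
    learning_rate: float = 0.05
    max_depth: int = 3
    min_leaf: int = 30
    row_subsample: float = 0.8
    feature_subsample_rule: str = "sqrt"
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 < self.row_subsample <= 1.0:
            raise ValueError("row_subsample must be in (0, 1]")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")


@dataclass(frozen=True)
class FoldAssignment:
    """Fold index per patient for k-fold stratified cross-validation."""

    fold: np.ndarray
    k: int
    seed: int

    def __post_init__(self):
        counts = np.bincount(self.fold, minlength=self.k)
        if np.any(counts == 0) or len(np.unique(self.fold)) != self.k:
            raise StratificationError("every fold must contain at least one patient")

    def __len__(self) -> int:
        return len(self.fold)


@dataclass
class OofPredictions:
    """Held-out probabilities, outcomes and fold bookkeeping for one model."""

    p: np.ndarray
    y: np.ndarray
    fold: np.ndarray
    tag: str = ""

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.fold = np.asarray(self.fold, dtype=int)
        if not (len(self.p) == len(self.y) == len(self.fold)):
            raise ValueError("p, y and fold must be aligned")

    def __len__(self) -> int:
        return len(self.p)


class Predictor:
    """A fitted model exposing P(stone) over a feature-aligned table."""

    def __init__(self, model, features: list[str], tag: str):
        self._model = model
        self.features = list(features)
        self.tag = tag

    def predict_proba1(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.features].to_numpy(dtype=float)
        return self._model.predict_proba(np.asarray(X, dtype=float))[:, 1]


def stratified_folds(outcomes: np.ndarray, k: int, seed: int) -> FoldAssignment:
    """Stratified k-fold assignment (per-fold class counts differ by <= 1)."""
    y = np.asarray(outcomes, dtype=int)
    if k < 2:
        raise StratificationError(f"k must be >= 2, got {k}")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise StratificationError("both outcome classes must be present")
    if counts.min() < k:
        raise StratificationError(
            f"minority class has {counts.min()} members, fewer than k={k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    fold = np.empty(len(y), dtype=int)
    for i, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        fold[test_idx] = i
    return FoldAssignment(fold=fold, k=k, seed=seed)


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise FitError("training outcomes contain a single class")


def fit_tree_ensemble(train: pd.DataFrame, features: list[str],
                      config: ModelConfig) -> Predictor:
    """Fit the gradient-boosted ensemble on ``train`` (must hold ``outcome``)."""
    y = train["outcome"].to_numpy(dtype=int)
    _check_two_classes(y)
    model = GradientBoostingClassifier(
        n_estimators=config.n_trees,
        learning_rate=config.learning_rate,
        max_depth=config.max_depth,
        min_samples_leaf=config.min_leaf,
        subsample=config.row_subsample,
        max_features=config.feature_subsample_rule,
        random_state=config.seed % (2**31),
    )
    model.fit(train[features].to_numpy(dtype=float), y)
    return Predictor(model, features, tag="gbm")


def fit_logistic_baseline(train: pd.DataFrame, features: list[str],
                          seed: int = 0) -> Predictor:
    """Logistic baseline with features standardized on the training rows only."""
    y = train["outcome"].to_numpy(dtype=int)
    _check_two_classes(y)
    X = train[features].to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    lr = LogisticRegression(max_iter=2000, random_state=seed % (2**31))
    lr.fit((X - mu) / sd, y)

    class _Standardized:
        def predict_proba(self, Z):
            return lr.predict_proba((np.asarray(Z, dtype=float) - mu) / sd)

    return Predictor(_Standardized(), features, tag="logistic")


def oof_predict(cohort: pd.DataFrame, features: list[str], config: ModelConfig,
                folds: FoldAssignment, model: str = "gbm", tag: str | None = None) -> OofPredictions:
    """Out-of-fold probabilities: each patient scored by the model that
    excluded that patient's fold from training."""
    if len(folds) != len(cohort):
        raise PairingError("fold assignment does not cover the cohort")
    y = cohort["outcome"].to_numpy(dtype=int)
    p = np.full(len(cohort), np.nan)
    for i in range(folds.k):
        test = folds.fold == i
        train = cohort.loc[~test]
        try:
            if model == "gbm":
                fold_cfg = ModelConfig(
                    n_trees=config.n_trees, learning_rate=config.learning_rate,
                    max_depth=config.max_depth, min_leaf=config.min_leaf,
                    row_subsample=config.row_subsample,
                    feature_subsample_rule=config.feature_subsample_rule,
                    seed=child_seed(config.seed, "fold", i))
                pred = fit_tree_ensemble(train, features, fold_cfg)
            elif model == "logistic":
                pred = fit_logistic_baseline(train, features, seed=child_seed(config.seed, "fold", i))
            else:
                raise ValueError(f"unknown model {model!r}")
        except FitError as err:
            raise FitError(f"fold {i}: {err}") from err
        p[test] = pred.predict_proba1(cohort.loc[test])
    return OofPredictions(p=p, y=y, fold=folds.fold.copy(),
                          tag=tag or f"{model}-{len(features)}f")


# ---------------------------------------------------------------------------
# discrimination and calibration statistics


def _as_scores(preds_or_p, y=None) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(preds_or_p, OofPredictions):
        return preds_or_p.p, preds_or_p.y
    return np.asarray(preds_or_p, dtype=float), np.asarray(y, dtype=int)


def roc_auc(preds_or_p, y=None) -> float:
    """Midrank Mann-Whitney AUC (ties get half credit)."""
    p, yy = _as_scores(preds_or_p, y)
    pos = yy == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: a class is empty")
    ranks = stats.rankdata(p)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _auc_rows(scores: np.ndarray, n_pos: int) -> np.ndarray:
    """Row-wise midrank AUC for a (B, n) score matrix whose first ``n_pos``
    columns are positives."""
    ranks = stats.rankdata(scores, axis=1)
    n0 = scores.shape[1] - n_pos
    return (ranks[:, :n_pos].sum(axis=1) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n0)


def bootstrap_auc_ci(preds_or_p, y=None, B: int = 1000, seed: int = 0,
                     alpha: float = 0.05) -> tuple[float, float]:
    """Class-stratified percentile bootstrap CI for the AUC."""
    p, yy = _as_scores(preds_or_p, y)
    rng = np.random.default_rng(seed % (2**31))
    pos, neg = p[yy == 1], p[yy == 0]
    bp = rng.choice(pos, size=(B, len(pos)), replace=True)
    bn = rng.choice(neg, size=(B, len(neg)), replace=True)
    aucs = _auc_rows(np.concatenate([bp, bn], axis=1), len(pos))
    lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def brier_score(preds_or_p, y=None) -> float:
    """Mean squared difference between probability and outcome."""
    p, yy = _as_scores(preds_or_p, y)
    return float(np.mean((p - yy) ** 2))


def calibration_table(preds_or_p, y=None, n_bins: int = 10) -> pd.DataFrame:
    """Quantile-binned calibration: per-bin mean predicted p vs observed rate."""
    p, yy = _as_scores(preds_or_p, y)
    edges = np.unique(np.quantile(p, np.linspace(0.0, 1.0, n_bins + 1)))
    if len(edges) < 2:  # all probabilities identical: one bin
        bin_idx = np.zeros(len(p), dtype=int)
        n_eff = 1
    else:
        bin_idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
        n_eff = len(edges) - 1
    rows = []
    for b in range(n_eff):
        mask = bin_idx == b
        if not mask.any():
            continue
        rows.append({
            "bin": b, "n": int(mask.sum()),
            "mean_predicted": float(p[mask].mean()),
            "observed_rate": float(yy[mask].mean()),
        })
    out = pd.DataFrame(rows)
    assert int(out["n"].sum()) == len(p)
    return out


# ---------------------------------------------------------------------------
# DeLong machinery


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x)


def _placements(p: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus per-positive (V10) and per-negative (V01) placement values."""
    pos, neg = p[y == 1], p[y == 0]
    m, n = len(pos), len(neg)
    tz = _midranks(np.concatenate([pos, neg]))
    tx, ty = _midranks(pos), _midranks(neg)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_auc_variance(preds_or_p, y=None) -> float:
    """DeLong variance estimate of a single AUC."""
    p, yy = _as_scores(preds_or_p, y)
    _, v10, v01 = _placements(p, yy)
    m, n = len(v10), len(v01)
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def delong_test(preds_a: OofPredictions, preds_b: OofPredictions) -> tuple[float, float, float]:
    """DeLong's paired test for two correlated AUCs on the same patients.

    Returns ``(delta_auc, z, p_value)`` with a two-sided normal p.
    A compared against itself has zero variance and p exactly 1.
    """
    if len(preds_a) != len(preds_b) or not np.array_equal(preds_a.y, preds_b.y):
        raise PairingError("DeLong test requires the same patients and outcomes for both models")
    y = preds_a.y
    auc_a, v10_a, v01_a = _placements(preds_a.p, y)
    auc_b, v10_b, v01_b = _placements(preds_b.p, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = auc_a - auc_b
    if var <= 0:
        # identical placement structure: no sampling variability in the delta
        return delta, 0.0, 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var)
    p_value = float(2.0 * stats.norm.sf(abs(z)))
    return float(delta), float(z), p_value


def paired_bootstrap_delta_auc(preds_a: OofPredictions, preds_b: OofPredictions,
                               B: int = 2000, seed: int = 0,
                               alpha: float = 0.05) -> tuple[float, tuple[float, float], float]:
    """Patient-level paired bootstrap of AUC(A) - AUC(B).

    Resamples patients with replacement (stratified by outcome so neither
    class empties), recomputes both AUCs per resample. Returns
    ``(mean_delta, (lo, hi), p)`` with p = 2*min(frac(delta* <= 0),
    frac(delta* >= 0)) clipped to [1/B, 1].
    """
    if len(preds_a) != len(preds_b) or not np.array_equal(preds_a.y, preds_b.y):
        raise PairingError("paired bootstrap requires identical patients and outcomes")
    y = preds_a.y
    rng = np.random.default_rng(seed % (2**31))
    pos_idx, neg_idx = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    bp = rng.choice(pos_idx, size=(B, len(pos_idx)), replace=True)
    bn = rng.choice(neg_idx, size=(B, len(neg_idx)), replace=True)
    idx = np.concatenate([bp, bn], axis=1)
    auc_a = _auc_rows(preds_a.p[idx], len(pos_idx))
    auc_b = _auc_rows(preds_b.p[idx], len(pos_idx))
    deltas = auc_a - auc_b
    lo, hi = np.quantile(deltas, [alpha / 2.0, 1.0 - alpha / 2.0])
    p = 2.0 * min(float(np.mean(deltas <= 0)), float(np.mean(deltas >= 0)))
    p = float(np.clip(p, 1.0 / B, 1.0))
    return float(deltas.mean()), (float(lo), float(hi)), p


# ---------------------------------------------------------------------------
# held-out permutation importance


def permutation_importance_heldout(cohort: pd.DataFrame, features: list[str],
                                   config: ModelConfig, folds: FoldAssignment,
                                   repeats: int = 30, seed: int = 0,
                                   model: str = "gbm") -> pd.DataFrame:
    """Held-out permutation importance.

    For each fold: fit on the other folds, score the test split, then for each
    feature permute the *test* column ``repeats`` times; the importance is
    AUC(original) minus the mean permuted AUC. Reported as mean and sd of the
    per-fold values.
    """
    y = cohort["outcome"].to_numpy(dtype=int)
    per_fold = np.zeros((folds.k, len(features)))
    for i in range(folds.k):
        test = folds.fold == i
        if model == "gbm":
            fold_cfg = ModelConfig(
                n_trees=config.n_trees, learning_rate=config.learning_rate,
                max_depth=config.max_depth, min_leaf=config.min_leaf,
                row_subsample=config.row_subsample,
                feature_subsample_rule=config.feature_subsample_rule,
                seed=child_seed(config.seed, "fold", i))
            pred = fit_tree_ensemble(cohort.loc[~test], features, fold_cfg)
        else:
            pred = fit_logistic_baseline(cohort.loc[~test], features,
                                         seed=child_seed(config.seed, "fold", i))
        X_test = cohort.loc[test, features].to_numpy(dtype=float)
        y_test = y[test]
        base_auc = roc_auc(pred.predict_proba1(X_test), y_test)
        rng = np.random.default_rng(child_seed(seed, "perm", i))
        for j in range(len(features)):
            perm_aucs = np.empty(repeats)
            for r in range(repeats):
                Xp = X_test.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                perm_aucs[r] = roc_auc(pred.predict_proba1(Xp), y_test)
            per_fold[i, j] = base_auc - perm_aucs.mean()
    return pd.DataFrame({
        "feature": features,
        "mean_delta_auc": per_fold.mean(axis=0),
        "sd_delta_auc": per_fold.std(axis=0, ddof=1),
    }).sort_values("mean_delta_auc", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# dichotomization and risk strata

# Default 9-variable binary model. The creatinine (>= 0.92 mg/dL) and pain
# duration (< 8 h) cutoffs are the conventional score thresholds; the remaining
# memberships/cutoffs are documented placeholders (the reference score's exact
# composition is not enumerated in the source material).
DEFAULT_BINARY_CUTOFFS: dict[str, tuple[float, str]] = {
    "sex": (0.5, "ge"),
    "stone_history": (0.5, "ge"),
    "pain_duration_h": (8.0, "lt"),
    "nausea": (0.5, "ge"),
    "vomiting": (0.5, "ge"),
    "cva_tenderness": (0.5, "ge"),
    "occult_blood_grade": (1.0, "ge"),
    "urine_rbc_hpf": (5.0, "ge"),
    "creatinine_mgdl": (0.92, "ge"),
}

_CUTOFF_OPS = {
    "ge": np.greater_equal,
    "gt": np.greater,
    "le": np.less_equal,
    "lt": np.less,
}


def binarize_features(cohort: pd.DataFrame,
                      cutoffs: dict[str, tuple[float, str]]) -> pd.DataFrame:
    """Replace listed features by 0/1 indicators; drop unlisted features.

    ``cutoffs`` maps feature -> (threshold, direction) with direction one of
    ge/gt/le/lt; the indicator is 1 where the comparison holds. ``patient_id``
    and ``outcome`` are preserved; row order is unchanged.
    """
    out = pd.DataFrame(index=cohort.index)
    if "patient_id" in cohort.columns:
        out["patient_id"] = cohort["patient_id"]
    for feat, (threshold, direction) in cutoffs.items():
        if direction not in _CUTOFF_OPS:
            raise ValueError(f"unknown cutoff direction {direction!r} for {feat}")
        out[feat] = _CUTOFF_OPS[direction](cohort[feat].to_numpy(dtype=float), threshold).astype(int)
    if "outcome" in cohort.columns:
        out["outcome"] = cohort["outcome"]
    return out


def risk_strata_table(preds_or_p, y=None,
                      strata_edges: list[float] = (0.0, 0.5, 0.7, 0.85, 1.0)) -> pd.DataFrame:
    """Counts and observed prevalence in half-open [lo, hi) probability strata.

    The final stratum is closed above so p = 1 is not lost.
    """
    p, yy = _as_scores(preds_or_p, y)
    edges = np.asarray(strata_edges, dtype=float)
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        rows.append({
            "stratum": f"[{edges[b]:g}, {edges[b + 1]:g})",
            "n": int(mask.sum()),
            "observed_prevalence": float(yy[mask].mean()) if mask.any() else np.nan,
        })
    out = pd.DataFrame(rows)
    assert int(out["n"].sum()) == len(p)
    return out
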