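"""Synthetic cohort generation for the urolithiasis diagnostic study.

The real study cohort (1000 ED patients with suspected stones, 85% CT-confirmed
prevalence) is not public, so every downstream analysis in this package runs on
synthetic cohorts that emulate the published class-conditional feature summaries:
truncated normals for roughly symmetric measurements (age, pain scale, body
temperature, specific gravity, creatinine), lognormals matched to the published
median/IQR for right-skewed ones (pain duration, CRP, urine RBC), a zero-inflated
Poisson for the near-degenerate urine WBC count, Bernoulli for binary findings,
and 0-4 ordinal grades for the two dipstick readings.

Two generating modes are supported:

``class_conditional``
    Draw the outcome first (Bernoulli at the target prevalence), then each
    feature independently from its class-conditional distribution. This mirrors
    how the published per-class summary table describes the data and is the
    default for benchmarking the pipeline.

``causal``
    Draw features from the pooled (prevalence-weighted mixture) marginals, build
    a log-odds risk score from optional linear terms plus *planted* non-linear
    effects (a tanh threshold crossing, a window peak, or a negative step above
    a cut), solve the intercept so the realised prevalence matches the target,
    and draw the outcome from the resulting probability. Planted effects give
    the explainability machinery a known ground truth to recover.

Features are sampled independently within class by default; an optional
Gaussian-copula correlation matrix induces dependence for sensitivity work.
All sampling is routed through per-feature quantile functions applied to
(possibly copula-correlated) uniforms, so truncation is exact for normals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats
from scipy.special import expit, ndtri

from .errors import SchemaError, SpecValidationError
from .seeds import child_rng

__all__ = [
    "FeatureSpec",
    "PlantedEffect",
    "CohortSpec",
    "FAMILIES",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "load_cohort_spec",
    "default_cohort_spec",
]

FAMILIES = ("history", "physical", "dipstick", "microscopy", "blood")
_KINDS = ("continuous", "binary", "ordinal")
_DISTS = ("normal", "lognormal", "count_zip")

# half-width of the central 50% of a standard normal: IQR = 2*z75*sigma
_Z75 = ndtri(0.75)


def _lognormal_from_quartiles(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Log-mean and log-sd of the lognormal matching a median and IQR."""
    return math.log(median), math.log(q3 / q1) / (2.0 * _Z75)


@dataclass
class FeatureSpec:
    """Distributional description of one predictor, per outcome class.

    ``stone_params`` / ``nostone_params`` hold, by kind/dist:

    - continuous-normal: ``{"mean", "sd"}``
    - continuous-lognormal: ``{"log_mean", "log_sd"}`` or ``{"median", "q1", "q3"}``
    - continuous-count_zip: ``{"p_zero", "lam"}`` (zero-inflated Poisson)
    - binary: ``{"p"}``
    - ordinal: ``{"probs": [...]}`` over integer grades 0..len-1
    """

    name: str
    family: str
    kind: str
    stone_params: dict
    nostone_params: dict
    support: tuple[float, float] | None = None
    dist: str = "normal"

    def __post_init__(self):
        prefix = f"features[{self.name}]"
        if self.family not in FAMILIES:
            raise SpecValidationError(f"{prefix}.family", f"must be one of {FAMILIES}")
        if self.kind not in _KINDS:
            raise SpecValidationError(f"{prefix}.kind", f"must be one of {_KINDS}")
        if self.kind == "continuous" and self.dist not in _DISTS:
            raise SpecValidationError(f"{prefix}.dist", f"must be one of {_DISTS}")
        for cls in ("stone_params", "nostone_params"):
            params = dict(getattr(self, cls))
            if self.kind == "continuous" and self.dist == "lognormal" and "median" in params:
                lm, ls = _lognormal_from_quartiles(params["median"], params["q1"], params["q3"])
                params = {"log_mean": lm, "log_sd": ls}
            setattr(self, cls, params)
            self._validate_params(params, f"{prefix}.{cls}")
        if self.kind == "continuous":
            if self.support is None:
                raise SpecValidationError(f"{prefix}.support", "continuous features need a support interval")
            lo, hi = self.support
            if not lo < hi:
                raise SpecValidationError(f"{prefix}.support", f"bounds must be ordered, got ({lo}, {hi})")
            self.support = (float(lo), float(hi))

    def _validate_params(self, params: dict, where: str) -> None:
        if self.kind == "binary":
            p = params.get("p")
            if p is None or not 0.0 <= p <= 1.0:
                raise SpecValidationError(f"{where}.p", f"event probability must be in [0,1], got {p}")
        elif self.kind == "ordinal":
            probs = params.get("probs")
            if probs is None or any(q < 0 or q > 1 for q in probs):
                raise SpecValidationError(f"{where}.probs", "category probabilities must be in [0,1]")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise SpecValidationError(f"{where}.probs", f"must sum to 1 (got {sum(probs)!r})")
        elif self.dist == "normal":
            if params.get("sd", 0.0) <= 0:
                raise SpecValidationError(f"{where}.sd", "sd must be > 0")
        elif self.dist == "lognormal":
            if params.get("log_sd", 0.0) <= 0:
                raise SpecValidationError(f"{where}.log_sd", "log_sd must be > 0")
        elif self.dist == "count_zip":
            pz = params.get("p_zero")
            if pz is None or not 0.0 <= pz <= 1.0:
                raise SpecValidationError(f"{where}.p_zero", f"must be in [0,1], got {pz}")
            if params.get("lam", -1.0) < 0:
                raise SpecValidationError(f"{where}.lam", "Poisson rate must be >= 0")

    # -- quantile functions -------------------------------------------------

    def ppf(self, u: np.ndarray, stone: bool) -> np.ndarray:
        """Quantile function of this feature's class-conditional law."""
        params = self.stone_params if stone else self.nostone_params
        if self.kind == "binary":
            return (u < params["p"]).astype(float)
        if self.kind == "ordinal":
            cum = np.cumsum(params["probs"])
            return np.searchsorted(cum, u, side="right").astype(float)
        lo, hi = self.support
        if self.dist == "normal":
            mean, sd = params["mean"], params["sd"]
            a, b = (lo - mean) / sd, (hi - mean) / sd
            return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)
        if self.dist == "lognormal":
            x = np.exp(params["log_mean"] + params["log_sd"] * ndtri(u))
            return np.clip(x, lo, hi)
        # zero-inflated Poisson: mass p_zero at 0, else Poisson(lam)
        pz, lam = params["p_zero"], params["lam"]
        x = np.zeros_like(u)
        tail = u >= pz
        if np.any(tail):
            x[tail] = stats.poisson.ppf((u[tail] - pz) / (1.0 - pz), lam)
        return np.clip(x, lo, hi)

    def truncated_moments(self, stone: bool) -> tuple[float, float]:
        """Theoretical (mean, sd) of the truncated normal actually sampled.

        Only defined for continuous-normal features; used by moment-recovery
        checks so that truncation is accounted for exactly.
        """
        if self.kind != "continuous" or self.dist != "normal":
            raise ValueError("truncated_moments is defined for continuous-normal features")
        params = self.stone_params if stone else self.nostone_params
        mean, sd = params["mean"], params["sd"]
        lo, hi = self.support
        a, b = (lo - mean) / sd, (hi - mean) / sd
        m, v = stats.truncnorm.stats(a, b, loc=mean, scale=sd, moments="mv")
        return float(m), float(np.sqrt(v))


@dataclass
class PlantedEffect:
    """A known non-linear log-odds effect injected in causal-mode generation.

    Shapes (all built from tanh steps with transition scale ``scale``,
    defaulting to 10% of the feature's pooled SD):

    - ``threshold_crossing``: magnitude * tanh((x - c) / scale) — the log-odds
      effect crosses zero at ``c``.
    - ``window_peak``: magnitude inside [lo, hi), ~0 outside (smooth edges).
    - ``negative_above``: -magnitude above ``c``, ~0 below.
    """

    feature: str
    shape: str
    magnitude: float
    c: float | None = None
    lo: float | None = None
    hi: float | None = None
    scale: float | None = None

    _SHAPES = ("threshold_crossing", "window_peak", "negative_above")

    def __post_init__(self):
        where = f"planted_effects[{self.feature}]"
        if self.shape not in self._SHAPES:
            raise SpecValidationError(f"{where}.shape", f"must be one of {self._SHAPES}")
        if self.shape in ("threshold_crossing", "negative_above") and self.c is None:
            raise SpecValidationError(f"{where}.c", "shape requires a cut point c")
        if self.shape == "window_peak" and (self.lo is None or self.hi is None or not self.lo < self.hi):
            raise SpecValidationError(f"{where}.lo/hi", "window_peak requires ordered lo < hi")

    def check_support(self, spec: "FeatureSpec") -> None:
        lo, hi = spec.support if spec.support else (-np.inf, np.inf)
        pts = [p for p in (self.c, self.lo, self.hi) if p is not None]
        for p in pts:
            if not lo <= p <= hi:
                raise SpecValidationError(
                    f"planted_effects[{self.feature}]",
                    f"cut point {p} outside feature support ({lo}, {hi})",
                )

    def log_odds(self, x: np.ndarray, scale: float) -> np.ndarray:
        s = self.scale if self.scale is not None else scale
        if self.shape == "threshold_crossing":
            return self.magnitude * np.tanh((x - self.c) / s)
        if self.shape == "window_peak":
            return self.magnitude * 0.5 * (np.tanh((x - self.lo) / s) - np.tanh((x - self.hi) / s))
        return -self.magnitude * 0.5 * (1.0 + np.tanh((x - self.c) / s))


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort."""

    n: int
    prevalence: float
    seed: int
    features: list[FeatureSpec]
    planted_effects: list[PlantedEffect] = dc_field(default_factory=list)
    linear_coefficients: dict[str, float] = dc_field(default_factory=dict)
    correlation: np.ndarray | None = None  # optional Gaussian-copula matrix

    def __post_init__(self):
        if self.n < 1:
            raise SpecValidationError("n", f"patient count must be >= 1, got {self.n}")
        if not 0.0 < self.prevalence < 1.0:
            raise SpecValidationError("prevalence", f"must be in (0,1), got {self.prevalence}")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            dup = sorted({x for x in names if names.count(x) > 1})
            raise SpecValidationError("features", f"duplicate feature names: {dup}")
        by_name = {f.name: f for f in self.features}
        for eff in self.planted_effects:
            if eff.feature not in by_name:
                raise SpecValidationError(
                    f"planted_effects[{eff.feature}]", "unknown feature name")
            eff.check_support(by_name[eff.feature])
        for name in self.linear_coefficients:
            if name not in by_name:
                raise SpecValidationError(f"linear_coefficients[{name}]", "unknown feature name")
        if self.correlation is not None:
            C = np.asarray(self.correlation, dtype=float)
            k = len(self.features)
            if C.shape != (k, k) or not np.allclose(C, C.T):
                raise SpecValidationError("correlation", f"must be a symmetric {k}x{k} matrix")
            self.correlation = C

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]


# ---------------------------------------------------------------------------
# generation


def _uniforms(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """(n, k) uniforms — iid, or Gaussian-copula correlated if configured."""
    n, k = spec.n, len(spec.features)
    if spec.correlation is None:
        return rng.random((n, k))
    z = rng.multivariate_normal(np.zeros(k), spec.correlation, size=n, method="cholesky")
    return stats.norm.cdf(z)


def _pooled_sd(f: FeatureSpec, prevalence: float, rng: np.random.Generator) -> float:
    # Monte-Carlo pooled SD; cheap and distribution-agnostic.
    u = rng.random(4096)
    cls = rng.random(4096) < prevalence
    x = np.where(cls, f.ppf(u, stone=True), f.ppf(u, stone=False))
    return float(np.std(x)) or 1.0


def generate_cohort(spec: CohortSpec, mode: str = "class_conditional") -> pd.DataFrame:
    """Generate a synthetic cohort as a DataFrame.

    Columns: ``patient_id``, the 17 (or configured) features, ``outcome``.
    Deterministic for a fixed ``spec.seed``.
    """
    if mode not in ("class_conditional", "causal"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "causal" and not spec.planted_effects:
        raise SpecValidationError("planted_effects", "causal mode requires at least one planted effect")

    rng = child_rng(spec.seed, "cohort", mode)
    u = _uniforms(spec, rng)

    if mode == "class_conditional":
        y = (rng.random(spec.n) < spec.prevalence).astype(int)
        cols = {}
        for j, f in enumerate(spec.features):
            x = np.empty(spec.n)
            pos = y == 1
            x[pos] = f.ppf(u[pos, j], stone=True)
            x[~pos] = f.ppf(u[~pos, j], stone=False)
            cols[f.name] = x
    else:
        # pooled marginals: per-patient, per-feature latent class indicator
        cols = {}
        for j, f in enumerate(spec.features):
            comp = rng.random(spec.n) < spec.prevalence
            cols[f.name] = np.where(comp, f.ppf(u[:, j], stone=True), f.ppf(u[:, j], stone=False))
        score = np.zeros(spec.n)
        mc_rng = child_rng(spec.seed, "cohort", "pooled-sd")
        for name, beta in spec.linear_coefficients.items():
            f = next(f for f in spec.features if f.name == name)
            x = cols[name]
            sd = _pooled_sd(f, spec.prevalence, mc_rng)
            score += beta * (x - np.mean(x)) / sd
        by_name = {f.name: f for f in spec.features}
        for eff in spec.planted_effects:
            f = by_name[eff.feature]
            sd = _pooled_sd(f, spec.prevalence, mc_rng)
            score += eff.log_odds(cols[eff.feature], scale=0.1 * sd)

        def realized(b0: float) -> float:
            return float(np.mean(expit(b0 + score))) - spec.prevalence

        b0 = optimize.brentq(realized, -30.0, 30.0)
        y = (rng.random(spec.n) < expit(b0 + score)).astype(int)

    df = pd.DataFrame(cols)
    df.insert(0, "patient_id", np.arange(spec.n))
    df["outcome"] = y
    return df


# ---------------------------------------------------------------------------
# CSV round trip


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort to CSV (UTF-8, header row, full float precision)."""
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path, feature_names: Sequence[str] | None = None) -> pd.DataFrame:
    """Read and schema-check a cohort CSV.

    Requires ``patient_id`` and ``outcome`` columns, no missing cells and
    numeric values throughout. If ``feature_names`` is given, the file must
    contain exactly those feature columns (order preserved from the file).
    """
    df = pd.read_csv(path)
    required = {"patient_id", "outcome"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise SchemaError(f"cohort file {path} is missing required columns: {missing}")
    if feature_names is not None:
        expected = ["patient_id", *feature_names, "outcome"]
        missing = sorted(set(expected) - set(df.columns))
        extra = sorted(set(df.columns) - set(expected))
        if missing or extra:
            raise SchemaError(
                f"cohort file {path} schema mismatch: missing columns {missing}, unexpected columns {extra}")
    if df.isna().any().any():
        rows, cols = np.nonzero(df.isna().to_numpy())
        first = [(int(r), df.columns[c]) for r, c in zip(rows[:5], cols[:5])]
        raise SchemaError(f"cohort file {path} has missing cells at (row, column): {first}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise SchemaError(f"cohort file {path}: column '{col}' is not numeric")
    if not set(np.unique(df["outcome"])) <= {0, 1}:
        raise SchemaError(f"cohort file {path}: outcome column must be 0/1")
    return df


# ---------------------------------------------------------------------------
# configuration files


def _feature_from_config(name: str, cfg: dict) -> FeatureSpec:
    return FeatureSpec(
        name=name,
        family=cfg["family"],
        kind=cfg["kind"],
        dist=cfg.get("dist", "normal"),
        stone_params=cfg["stone"],
        nostone_params=cfg["nostone"],
        support=tuple(cfg["support"]) if "support" in cfg else None,
    )


def load_cohort_spec(path: str | Path, n: int | None = None, seed: int | None = None,
                     prevalence: float | None = None) -> CohortSpec:
    """Load a CohortSpec from YAML, optionally overriding n/seed/prevalence."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    features = [_feature_from_config(name, fcfg) for name, fcfg in cfg["features"].items()]
    planted = [PlantedEffect(**e) for e in cfg.get("planted_effects", [])]
    return CohortSpec(
        n=int(n if n is not None else cfg.get("n", 1000)),
        prevalence=float(prevalence if prevalence is not None else cfg.get("prevalence", 0.85)),
        seed=int(seed if seed is not None else cfg.get("seed", 0)),
        features=features,
        planted_effects=planted,
        linear_coefficients=cfg.get("linear_coefficients", {}) or {},
    )


def default_cohort_spec(n: int = 1000, seed: int = 0, prevalence: float = 0.85,
                        planted_effects: list[PlantedEffect] | None = None,
                        linear_coefficients: dict[str, float] | None = None) -> CohortSpec:
    """The shipped 17-feature cohort specification (study-population defaults)."""
    ref = resources.files("diagxai.data").joinpath("study_cohort.yaml")
    with resources.as_file(ref) as path:
        spec = load_cohort_spec(path, n=n, seed=seed, prevalence=prevalence)
    if planted_effects:
        spec = CohortSpec(
            n=spec.n, prevalence=spec.prevalence, seed=spec.seed, features=spec.features,
            planted_effects=planted_effects,
            linear_coefficients=linear_coefficients or {},
        )
    return spec
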