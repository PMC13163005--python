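"""Prevalence projection of threshold operating points via Bayes' rule.

A probability threshold applied as a binary test has a sensitivity/specificity
pair (an operating point) estimated from held-out predictions. Its predictive
values at any baseline prevalence follow from the likelihood ratios:

    LR+ = Se / (1 - Sp),   LR- = (1 - Se) / Sp
    posterior odds(+) = LR+ * pi / (1 - pi)   ->  PPV
    NPV = Sp (1 - pi) / (Sp (1 - pi) + (1 - Se) pi)

The high arm calls a test positive when p >= tau_high; the low arm calls a
test negative when p <= tau_low (boundary included in both, unlike the
resolution cascade's strict inequalities — a deliberate, documented
difference). Projections at the source prevalence reproduce the empirical
PPV/NPV exactly (closed-loop identity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OperatingPoint",
    "operating_point",
    "project_ppv_npv",
    "projection_table",
]


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    arm: str                 # 'high' or 'low'
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def lr_pos(self) -> float:
        se, sp = self.sensitivity, self.specificity
        return se / (1.0 - sp) if sp < 1.0 else float("inf")

    @property
    def lr_neg(self) -> float:
        se, sp = self.sensitivity, self.specificity
        return (1.0 - se) / sp if sp > 0.0 else float("inf")

    @property
    def defined(self) -> bool:
        return (self.tp + self.fn) > 0 and (self.tn + self.fp) > 0


def operating_point(preds_or_p, y=None, tau: float = 0.90, arm: str = "high") -> OperatingPoint:
    """Empirical 2x2 table of a probability threshold.

    High arm: test positive iff p >= tau. Low arm: test negative iff p <= tau
    (i.e. positive iff p > tau).
    """
    from .models import _as_scores

    p, yy = _as_scores(preds_or_p, y)
    if arm == "high":
        test_pos = p >= tau
    elif arm == "low":
        test_pos = p > tau
    else:
        raise ValueError(f"arm must be 'high' or 'low', got {arm!r}")
    pos = yy == 1
    return OperatingPoint(
        threshold=float(tau), arm=arm,
        tp=int(np.sum(test_pos & pos)), fp=int(np.sum(test_pos & ~pos)),
        fn=int(np.sum(~test_pos & pos)), tn=int(np.sum(~test_pos & ~pos)))


def project_ppv_npv(op: OperatingPoint | tuple[float, float], prevalence: float) -> tuple[float, float]:
    """Bayes-projected (PPV, NPV) of an operating point at a new prevalence.

    Accepts an OperatingPoint or a raw (sensitivity, specificity) pair.
    Undefined denominators yield nan.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    if isinstance(op, OperatingPoint):
        se, sp = op.sensitivity, op.specificity
    else:
        se, sp = op
    pi = prevalence
    ppv_den = se * pi + (1.0 - sp) * (1.0 - pi)
    npv_den = sp * (1.0 - pi) + (1.0 - se) * pi
    ppv = se * pi / ppv_den if ppv_den > 0 else float("nan")
    npv = sp * (1.0 - pi) / npv_den if npv_den > 0 else float("nan")
    return ppv, npv


def projection_table(op_high: OperatingPoint, op_low: OperatingPoint,
                     grid) -> pd.DataFrame:
    """PPV of the high arm and NPV of the low arm across a prevalence grid.

    Monotonicity (PPV non-decreasing, NPV non-increasing in prevalence, given
    LR+ > 1 > LR-) is asserted on the computed table.
    """
    grid = np.asarray(grid, dtype=float)
    rows = []
    for pi in grid:
        ppv, _ = project_ppv_npv(op_high, pi)
        _, npv = project_ppv_npv(op_low, pi)
        rows.append({
            "prevalence": float(pi),
            "ppv_high": ppv,
            "npv_low": npv,
            "lr_pos_high": op_high.lr_pos,
            "lr_neg_low": op_low.lr_neg,
        })
    out = pd.DataFrame(rows).sort_values("prevalence", ignore_index=True)
    if op_high.lr_pos > 1.0:
        assert np.all(np.diff(out["ppv_high"]) >= -1e-12)
    if op_low.lr_neg < 1.0:
        assert np.all(np.diff(out["npv_low"]) <= 1e-12)
    return out
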