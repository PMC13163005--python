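"""Binary entropy, stage gains, trajectories and the resolution cascade."""

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st
from scipy import stats as sps

import diagxai as d
from diagxai.errors import DomainError, PairingError
from diagxai.models import OofPredictions


def _stage_preds(P, y):
    return [OofPredictions(p=P[:, s], y=y, fold=np.zeros(len(y), dtype=int),
                           tag=f"stage{s+1}") for s in range(P.shape[1])]


class TestBinaryEntropy:
    def test_reference_values(self):
        assert d.binary_entropy(0.5) == pytest.approx(1.0, abs=1e-12)
        assert d.binary_entropy(0.85) == pytest.approx(0.610, abs=5e-4)
        assert d.binary_entropy(0.0) == 0.0
        assert d.binary_entropy(1.0) == 0.0

    def test_matches_scipy_on_dense_grid(self):
        p = np.linspace(0.0, 1.0, 10_001)
        ours = d.binary_entropy(p)
        oracle = np.array([sps.entropy([q, 1 - q], base=2) for q in p[::100]])
        assert np.max(np.abs(ours[::100] - oracle)) < 1e-12

    @given(st.floats(0.0, 1.0, allow_nan=False))
    def test_symmetry_and_bounds(self, p):
        assume(1.0 - (1.0 - p) == p)  # 1-p must be representable losslessly
        h = d.binary_entropy(p)
        assert h == d.binary_entropy(1.0 - p)
        assert 0.0 <= h <= 1.0

    def test_domain_error_outside_unit_interval(self):
        with pytest.raises(DomainError):
            d.binary_entropy(1.2)
        with pytest.raises(DomainError):
            d.binary_entropy([-0.1, 0.5])


class TestPriorEntropy:
    @pytest.mark.parametrize("prev, expected", [
        (0.85, 0.610), (0.5, 1.0), (0.4, 0.971)])
    def test_values(self, prev, expected):
        n = 1000
        y = np.zeros(n, dtype=int)
        y[: int(round(prev * n))] = 1
        pi, h0 = d.prior_entropy(y)
        assert pi == pytest.approx(prev)
        assert h0 == pytest.approx(expected, abs=5e-4)


class TestStageGains:
    def test_uninformative_stages_give_zero(self):
        marg, cum = d.stage_gains([0.61, 0.61, 0.61], 0.61)
        assert marg == [0.0, 0.0, 0.0]
        assert cum == [0.0, 0.0, 0.0]

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=8),
           st.floats(0.1, 1.0))
    def test_marginals_telescope_to_cumulative(self, mean_h, h0):
        marg, cum = d.stage_gains(mean_h, h0)
        for s in range(len(mean_h)):
            assert sum(marg[: s + 1]) == pytest.approx(cum[s], abs=1e-9)

    def test_stage1_gain_ignores_later_stages(self):
        """No look-ahead: relabeling later stages leaves stage-1 gain fixed."""
        marg_a, _ = d.stage_gains([0.5, 0.4, 0.3], 0.61)
        marg_b, _ = d.stage_gains([0.5, 0.3, 0.4], 0.61)
        assert marg_a[0] == marg_b[0]


class TestStageModels:
    def test_stage5_equals_full_17_feature_run(self, small_cohort, fast_config):
        y = small_cohort["outcome"].to_numpy(dtype=int)
        folds = d.stratified_folds(y, k=5, seed=2)
        stages = d.default_stages()
        assert [len(s.features) for s in stages] == [5, 9, 12, 15, 17]
        # strict nesting
        for a, b in zip(stages, stages[1:]):
            assert set(a.features) < set(b.features)
        stage_preds = d.fit_stage_models(small_cohort, stages, fast_config, folds)
        full = d.oof_predict(small_cohort, list(stages[-1].features), fast_config, folds)
        assert np.array_equal(stage_preds[-1].p, full.p)
        for sp in stage_preds:
            assert np.array_equal(sp.fold, folds.fold)

    def test_summary_reports_all_stages(self, small_cohort, fast_config):
        y = small_cohort["outcome"].to_numpy(dtype=int)
        folds = d.stratified_folds(y, k=5, seed=2)
        stages = d.default_stages()
        stage_preds = d.fit_stage_models(small_cohort, stages, fast_config, folds)
        _, h0 = d.prior_entropy(y)
        report = d.stage_entropy_summary(stage_preds, h0, stages=stages)
        assert list(report["stage"]) == [1, 2, 3, 4, 5]
        assert list(report["n_features"]) == [5, 9, 12, 15, 17]
        # telescoping holds on real model output too
        assert report["marginal_gain_pct"].sum() == pytest.approx(
            report["cumulative_gain_pct"].iloc[-1], abs=1e-9)
        # cumulative cascade counts are non-decreasing
        assert report["rule_in_n"].is_monotonic_increasing
        assert report["low_prob_n"].is_monotonic_increasing


class TestTrajectories:
    def test_identical_predictions_identical_series(self):
        y = np.array([1] * 6 + [0] * 4)
        P = np.tile(np.full((10, 1), 0.7), (1, 3))
        traj = d.trajectories_by_outcome(_stage_preds(P, y))
        assert np.allclose(traj["mean_h_stone"], traj["mean_h_nostone"])
        assert ((traj[["mean_h_stone", "mean_h_nostone"]] >= 0).all().all()
                and (traj[["mean_h_stone", "mean_h_nostone"]] <= 1).all().all())

    def test_stone_series_decreases_on_calibrated_high_prevalence_cohort(self):
        """As stages sharpen a calibrated model at 85% prevalence, confirmed
        stone patients accumulate confirmatory evidence: their entropy falls."""
        rng = np.random.default_rng(9)
        n, pi = 5000, 0.85
        y = (rng.random(n) < pi).astype(int)
        logit0 = np.log(pi / (1 - pi))
        P = np.empty((n, 5))
        for s, scale in enumerate([0.5, 1.0, 1.5, 2.0, 2.5]):
            eta = logit0 + scale * np.where(y == 1, 1.0, -1.0) + rng.normal(0, 0.5, n)
            P[:, s] = 1 / (1 + np.exp(-eta))
        traj = d.trajectories_by_outcome(_stage_preds(P, y))
        assert traj["mean_h_stone"].is_monotonic_decreasing


class TestSequentialResolution:
    def test_everyone_high_at_stage_one(self):
        y = np.ones(5, dtype=int)
        P = np.full((5, 5), 0.95)
        res = d.sequential_resolution(P, d.ResolutionThresholds(), outcomes=y)
        assert np.all(res.resolution_stage == 1)
        assert np.all(res.arm == "high")
        assert res.cumulative_resolved_frac[0] == 1.0
        assert res.unresolved_frac == 0.0

    def test_nobody_resolves_at_half(self):
        y = np.array([1] * 17 + [0] * 3)
        P = np.full((20, 5), 0.5)
        res = d.sequential_resolution(P, d.ResolutionThresholds(), outcomes=y)
        assert res.unresolved_frac == 1.0
        assert res.unresolved_prevalence == pytest.approx(y.mean())

    def test_hand_traced_four_patient_toy(self):
        """First-threshold-crossing scan: stages (1, 1, 2, unresolved)."""
        P = np.array([
            [0.95, 0.95, 0.95, 0.95, 0.95],   # high at stage 1
            [0.10, 0.10, 0.10, 0.10, 0.10],   # low at stage 1
            [0.50, 0.92, 0.30, 0.30, 0.30],   # high at stage 2, then ignored
            [0.50, 0.50, 0.50, 0.50, 0.50],   # never resolves
        ])
        y = np.array([1, 0, 1, 1])
        res = d.sequential_resolution(P, d.ResolutionThresholds(0.90, 0.20), outcomes=y)
        assert res.resolution_stage.tolist() == [1, 1, 2, 0]
        assert res.arm.tolist() == ["high", "low", "high", "none"]
        assert res.final_class.tolist() == [1, 0, 1, -1]
        assert res.cumulative_resolved_frac.tolist() == [0.5, 0.75, 0.75, 0.75, 0.75]

    def test_strict_inequalities_at_thresholds(self):
        P = np.array([[0.90], [0.20], [0.9000001], [0.1999999]])
        res = d.sequential_resolution(P, d.ResolutionThresholds(0.90, 0.20),
                                      outcomes=np.array([1, 0, 1, 0]))
        assert res.resolution_stage.tolist() == [0, 0, 1, 1]

    @given(st.integers(0, 10_000))
    def test_conservation_and_monotonicity_random(self, seed):
        rng = np.random.default_rng(seed)
        n, S = rng.integers(1, 40), rng.integers(1, 6)
        P = rng.random((n, S))
        y = rng.integers(0, 2, n)
        thr = d.ResolutionThresholds(0.90, 0.20)
        res = d.sequential_resolution(P, thr, outcomes=y)
        # conservation at every stage
        assert np.all(np.diff(res.cumulative_resolved_frac) >= 0)
        resolved = res.resolution_stage > 0
        assert resolved.sum() + (~resolved).sum() == n
        assert res.cumulative_resolved_frac[-1] == pytest.approx(resolved.mean())
        # widening the thresholds inward never decreases resolved counts
        wide = d.sequential_resolution(P, d.ResolutionThresholds(0.85, 0.30), outcomes=y)
        n_stages = P.shape[1]
        for s in range(1, n_stages + 1):
            strict_n = np.sum((res.resolution_stage > 0) & (res.resolution_stage <= s))
            wide_n = np.sum((wide.resolution_stage > 0) & (wide.resolution_stage <= s))
            assert wide_n >= strict_n

    def test_adversarial_boundary_matrix(self):
        """Probabilities exactly on both thresholds never resolve."""
        P = np.tile([0.90, 0.20], (6, 3))[:, :3]
        res = d.sequential_resolution(P, d.ResolutionThresholds(0.90, 0.20),
                                      outcomes=np.tile([0, 1], 3))
        assert res.unresolved_frac == 1.0

    def test_inconsistent_patient_sets_rejected(self):
        a = OofPredictions(p=[0.5, 0.6], y=[1, 0], fold=[0, 0])
        b = OofPredictions(p=[0.5, 0.6], y=[0, 1], fold=[0, 0])
        with pytest.raises(PairingError):
            d.sequential_resolution([a, b], d.ResolutionThresholds())


class TestCascadeSummary:
    def test_partition_and_prevalence_ordering(self):
        rng = np.random.default_rng(3)
        n = 4000
        y = (rng.random(n) < 0.85).astype(int)
        # calibrated-ish stage probabilities concentrating across stages
        P = np.empty((n, 5))
        logit0 = np.log(0.85 / 0.15)
        for s, scale in enumerate([0.2, 0.4, 0.6, 0.8, 1.0]):
            eta = logit0 + scale * np.where(y == 1, 1.0, -1.0) + rng.normal(0, 1.0, n)
            P[:, s] = 1 / (1 + np.exp(-eta))
        res = d.sequential_resolution(P, d.ResolutionThresholds(), outcomes=y)
        summary = d.cascade_summary(res, y)
        assert sum(g["n"] for g in summary.values()) == n
        # unresolved patients sit between the two arms in observed prevalence
        assert (summary["low_probability"]["stone_prevalence"]
                < summary["unresolved"]["stone_prevalence"]
                < summary["rule_in"]["stone_prevalence"])

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            d.ResolutionThresholds(0.2, 0.9)
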