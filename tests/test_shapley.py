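"""Interventional attribution: oracle equivalence, additivity, curves, tables."""

import numpy as np
import pandas as pd
import pytest

import diagxai as d
from diagxai.errors import ConstantFeatureError
from diagxai.models import Predictor
from diagxai.shapley import _zero_crossings

from conftest import naive_interventional_phi


class _FnPredictor(Predictor):
    """Adapter turning a plain array->probability function into a Predictor."""

    def __init__(self, fn, features):
        self._fn = fn
        self.features = list(features)
        self.tag = "fn"

    def predict_proba1(self, X):
        if isinstance(X, pd.DataFrame):
            X = X[self.features].to_numpy(dtype=float)
        return self._fn(np.asarray(X, dtype=float))


def _cohort_from(X, features):
    df = pd.DataFrame(X, columns=features)
    df.insert(0, "patient_id", np.arange(len(df)))
    df["outcome"] = (np.arange(len(df)) % 2).astype(int)
    return df


class TestBackground:
    def test_full_cohort_background(self, small_cohort):
        bg = d.sample_background(small_cohort, m=len(small_cohort), seed=0)
        assert np.array_equal(bg.indices, np.arange(len(small_cohort)))

    def test_unique_indices_and_determinism(self, small_cohort):
        bg1 = d.sample_background(small_cohort, m=100, seed=7)
        bg2 = d.sample_background(small_cohort, m=100, seed=7)
        assert len(np.unique(bg1.indices)) == 100
        assert np.array_equal(bg1.indices, bg2.indices)

    def test_oversized_background_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="exceeds cohort size"):
            d.sample_background(small_cohort, m=len(small_cohort) + 1, seed=0)


class TestAttribution:
    def test_additive_closed_form(self):
        """f(x) = 0.2 + 0.3 x1: phi1 = 0.3 (x1 - background mean of x1)."""
        features = ["x1", "x2"]
        X = np.array([[0.9, 5.0], [0.1, 2.0]])
        bg_X = np.array([[0.4, 1.0], [0.6, 3.0]])  # x1 background mean 0.5
        cohort = _cohort_from(np.vstack([X, bg_X]), features)
        pred = _FnPredictor(lambda A: 0.2 + 0.3 * A[:, 0], features)
        bg = d.BackgroundSample(indices=np.array([2, 3]), seed=0)
        attr = d.interventional_contributions(pred, cohort, bg)
        assert attr.phi.loc[0, "x1"] == pytest.approx(0.3 * (0.9 - 0.5), abs=1e-12)
        assert attr.phi.loc[1, "x1"] == pytest.approx(0.3 * (0.1 - 0.5), abs=1e-12)
        assert np.allclose(attr.phi["x2"], 0.0)

    def test_null_player_gets_zero(self, small_cohort, fast_config):
        features = ["age", "creatinine_mgdl", "crp_mgdl"]
        pred = _FnPredictor(lambda A: 1 / (1 + np.exp(-(A[:, 0] - 48) / 10)), features)
        bg = d.sample_background(small_cohort, m=20, seed=1)
        attr = d.interventional_contributions(pred, small_cohort, bg)
        assert np.allclose(attr.phi["creatinine_mgdl"], 0.0)
        assert np.allclose(attr.phi["crp_mgdl"], 0.0)

    def test_matches_naive_oracle_on_fitted_tree(self, fast_config):
        """Production path equals the brute-force loop to 1e-12 (n<=50, m<=20)."""
        rng = np.random.default_rng(11)
        n, feats = 50, ["a", "b", "c"]
        X = rng.normal(0, 1, (n, 3))
        y = ((X[:, 0] + 0.5 * X[:, 1] * X[:, 2] + rng.normal(0, 0.5, n)) > 0).astype(int)
        df = pd.DataFrame(X, columns=feats)
        df.insert(0, "patient_id", np.arange(n))
        df["outcome"] = y
        pred = d.fit_tree_ensemble(df, feats, fast_config)
        bg = d.sample_background(df, m=20, seed=2)
        attr = d.interventional_contributions(pred, df, bg)
        oracle = naive_interventional_phi(pred.predict_proba1, X, X[bg.indices])
        assert np.max(np.abs(attr.phi.to_numpy() - oracle)) < 1e-12

    def test_probability_scale_bound(self, small_cohort, fast_config):
        feats = [c for c in small_cohort.columns if c not in ("patient_id", "outcome")]
        pred = d.fit_tree_ensemble(small_cohort, feats, fast_config)
        bg = d.sample_background(small_cohort, m=30, seed=3)
        attr = d.interventional_contributions(pred, small_cohort, bg)
        assert (attr.phi.abs().to_numpy() <= 1.0).all()
        assert np.isfinite(attr.phi.to_numpy()).all()


class TestReconstruction:
    def test_additive_model_reconstructs_exactly(self, small_cohort):
        feats = ["age", "creatinine_mgdl"]
        pred = _FnPredictor(
            lambda A: 0.3 + 0.004 * (A[:, 0] - 48) + 0.1 * np.tanh(A[:, 1] - 1.0), feats)
        bg = d.BackgroundSample(indices=np.arange(len(small_cohort)), seed=0)
        attr = d.interventional_contributions(pred, small_cohort, bg)
        gaps, mean_gap = d.reconstruction_error(attr)
        assert mean_gap < 1e-12
        assert np.max(gaps) < 1e-12

    def test_interaction_model_reports_positive_gap(self, small_cohort, fast_config):
        feats = ["age", "creatinine_mgdl"]
        pred = _FnPredictor(
            lambda A: 1 / (1 + np.exp(-(A[:, 0] - 48) * (A[:, 1] - 1.0))), feats)
        bg = d.sample_background(small_cohort, m=50, seed=4)
        attr = d.interventional_contributions(pred, small_cohort, bg)
        _, mean_gap = d.reconstruction_error(attr)
        assert mean_gap > 0  # reported, not asserted small


class TestDependenceCurve:
    def test_linear_interpolation_of_sign_change(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        trend = np.array([-1.0, -0.5, 0.5, 1.0])
        assert _zero_crossings(x, trend) == [pytest.approx(2.5)]

    def test_all_positive_trend_has_no_crossing(self):
        assert _zero_crossings(np.arange(5.0), np.ones(5)) == []

    def test_constant_feature_rejected(self, small_cohort):
        cohort = small_cohort.copy()
        cohort["flat"] = 1.0
        attr = d.AttributionMatrix(
            phi=pd.DataFrame({"flat": np.zeros(len(cohort))}, index=cohort.index),
            base_value=0.5, prediction=np.full(len(cohort), 0.5))
        with pytest.raises(ConstantFeatureError):
            d.dependence_curve(attr, cohort, "flat")

    def test_window_default_floor(self, small_cohort, fast_config):
        feats = ["age", "creatinine_mgdl"]
        pred = _FnPredictor(lambda A: 1 / (1 + np.exp(-(A[:, 1] - 0.95) * 5)), feats)
        bg = d.sample_background(small_cohort, m=30, seed=5)
        attr = d.interventional_contributions(pred, small_cohort, bg)
        curve = d.dependence_curve(attr, small_cohort, "creatinine_mgdl")
        assert curve.window == max(15, int(np.ceil(0.05 * len(small_cohort))))
        # a monotone-increasing effect through the background mean crosses once
        assert len(curve.zero_crossings) >= 1


class TestStratifiedTable:
    def test_single_interval_reproduces_whole_cohort(self, small_cohort):
        attr = d.AttributionMatrix(
            phi=pd.DataFrame({"age": np.linspace(-0.2, 0.2, len(small_cohort))},
                             index=small_cohort.index),
            base_value=0.5, prediction=np.full(len(small_cohort), 0.5))
        tab = d.stratified_contribution_table(attr, small_cohort, "age", [0, 200])
        assert len(tab) == 1
        assert tab.loc[0, "n"] == len(small_cohort)
        assert tab.loc[0, "mean_phi"] == pytest.approx(attr.phi["age"].mean())

    def test_counts_conserve_n(self, small_cohort):
        attr = d.AttributionMatrix(
            phi=pd.DataFrame({"age": np.zeros(len(small_cohort))}, index=small_cohort.index),
            base_value=0.5, prediction=np.full(len(small_cohort), 0.5))
        tab = d.stratified_contribution_table(attr, small_cohort, "age", [0, 30, 50, 70, 200])
        assert tab["n"].sum() == len(small_cohort)

    def test_planted_negative_signal_recovered_in_strata(self, fast_config):
        """With a negative-above effect on CRP, mean contribution above the cut
        is negative (sign recovery on a causal synthetic cohort)."""
        eff = d.PlantedEffect(feature="crp_mgdl", shape="negative_above",
                              magnitude=2.5, c=1.0)
        spec = d.default_cohort_spec(n=2000, seed=31, prevalence=0.5,
                                     planted_effects=[eff])
        cohort = d.generate_cohort(spec, mode="causal")
        feats = [c for c in cohort.columns if c not in ("patient_id", "outcome")]
        pred = d.fit_tree_ensemble(cohort, feats, d.ModelConfig(seed=8))
        bg = d.sample_background(cohort, m=100, seed=9)
        attr = d.interventional_contributions(pred, cohort, bg, features=["crp_mgdl"])
        tab = d.stratified_contribution_table(attr, cohort, "crp_mgdl", [0.0, 1.0, 40.0])
        assert tab.loc[1, "mean_phi"] < 0
        assert tab.loc[1, "mean_phi"] < tab.loc[0, "mean_phi"]


class TestSubgroupSummary:
    def test_independent_features_have_near_zero_rank_correlation(self):
        rng = np.random.default_rng(12)
        n = 2000
        cohort = pd.DataFrame({
            "patient_id": np.arange(n),
            "crp": rng.lognormal(-2.0, 1.0, n),
            "le": (rng.random(n) < 0.15).astype(float),
            "outcome": (rng.random(n) < 0.5).astype(int),
        })
        attr = d.AttributionMatrix(
            phi=pd.DataFrame({"crp": rng.normal(0, 0.05, n), "le": rng.normal(0, 0.05, n)},
                             index=cohort.index),
            base_value=0.5, prediction=np.full(n, 0.5))
        res = d.subgroup_contribution_summary(attr, cohort, "crp", 3.0, "le")
        assert abs(res["spearman_raw"]["rho"]) < 0.05
        assert abs(res["spearman_phi"]["rho"]) < 0.05
        assert sum(g["n"] for g in res["subgroups"].values()) == n

    def test_constant_second_feature_flagged(self):
        n = 50
        cohort = pd.DataFrame({"patient_id": np.arange(n), "a": np.arange(n, dtype=float),
                               "b": np.zeros(n), "outcome": np.tile([0, 1], 25)})
        attr = d.AttributionMatrix(
            phi=pd.DataFrame({"a": np.linspace(-1, 1, n) * 0.1, "b": np.zeros(n)},
                             index=cohort.index),
            base_value=0.5, prediction=np.full(n, 0.5))
        res = d.subgroup_contribution_summary(attr, cohort, "a", 25.0, "b")
        assert res["spearman_raw"]["constant_input"]
        assert np.isnan(res["spearman_raw"]["rho"])


class TestBackgroundSensitivity:
    def test_single_signal_cohort_stable_top_feature(self, fast_config):
        rng = np.random.default_rng(13)
        n = 300
        cohort = pd.DataFrame({
            "patient_id": np.arange(n),
            "signal": rng.normal(0, 1, n),
            "noise1": rng.normal(0, 1, n),
            "noise2": rng.normal(0, 1, n),
        })
        cohort["outcome"] = (cohort["signal"] + rng.normal(0, 0.3, n) > 0).astype(int)
        pred = d.fit_tree_ensemble(cohort, ["signal", "noise1", "noise2"], fast_config)
        res = d.background_size_sensitivity(pred, cohort, sizes=(20, 50, 100), seed=14)
        for table in res["rankings"].values():
            assert table.index[0] == "signal"
        res2 = d.background_size_sensitivity(pred, cohort, sizes=(20, 50, 100), seed=14)
        for m in res["rankings"]:
            pd.testing.assert_series_equal(res["rankings"][m], res2["rankings"][m])


class TestWaterfall:
    def _attr(self, cohort):
        rng = np.random.default_rng(15)
        feats = [c for c in cohort.columns if c not in ("patient_id", "outcome")]
        phi = pd.DataFrame(rng.normal(0, 0.05, (len(cohort), len(feats))),
                           columns=feats, index=cohort.index)
        return d.AttributionMatrix(phi=phi, base_value=0.6,
                                   prediction=np.full(len(cohort), 0.7))

    def test_no_other_bucket_when_top_k_covers_all(self, small_cohort):
        attr = self._attr(small_cohort)
        wf = d.waterfall(attr, 0, small_cohort, top_k=30)
        assert wf.other == 0.0
        assert len(wf.entries) == attr.phi.shape[1]

    def test_listed_plus_other_sums_exactly(self, small_cohort):
        attr = self._attr(small_cohort)
        wf = d.waterfall(attr, 5, small_cohort, top_k=4)
        total = sum(phi for _, _, phi in wf.entries) + wf.other
        assert total == pytest.approx(attr.phi.loc[5].sum(), abs=1e-12)
        assert wf.reconstructed == pytest.approx(attr.base_value + total, abs=1e-12)

    def test_conflicting_signals_rank_top_two(self, small_cohort):
        attr = self._attr(small_cohort)
        attr.phi.loc[3, "creatinine_mgdl"] = 0.4
        attr.phi.loc[3, "crp_mgdl"] = -0.38
        wf = d.waterfall(attr, 3, small_cohort, top_k=5)
        top2 = {f for f, _, _ in wf.entries[:2]}
        assert top2 == {"creatinine_mgdl", "crp_mgdl"}
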