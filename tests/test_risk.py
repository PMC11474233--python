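"""Risk geometry: distances, the y = x rule, metrics, clustering, voting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from akiplanner import compute_metrics, kmeans_treatments, majority_vote, risk_point
from akiplanner.config import GROUP_NEG, GROUP_POS, PLAN_PARAMS
from akiplanner.risk import (
    PlanScaler,
    RiskPoint,
    classify,
    recommend,
    risk_points,
)


def _unit_scaler(p, names=None):
    return PlanScaler(
        mean=np.zeros(p),
        sd=np.ones(p),
        param_names=list(names) if names else [f"x{i}" for i in range(p)],
    )


class TestRiskPoint:
    def test_plan_at_prototype_has_zero_distance(self):
        s = _unit_scaler(3)
        pt = risk_point([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [4.0, 5.0, 6.0], s)
        assert pt.d_minus == 0.0 and pt.d_plus > 0

    def test_symmetric_prototypes_equidistant(self):
        s = _unit_scaler(2)
        pt = risk_point([0.0, 0.0], [1.0, 1.0], [-1.0, -1.0], s)
        assert pt.d_minus == pytest.approx(pt.d_plus)

    def test_hand_euclidean_toy(self):
        """plan (100, 1) vs prototypes (103, 1) and (100, 5), unit SDs."""
        s = _unit_scaler(2)
        pt = risk_point([100.0, 1.0], [103.0, 1.0], [100.0, 5.0], s)
        assert (pt.d_minus, pt.d_plus) == (3.0, 4.0)

    def test_unfitted_scaler_rejected(self):
        with pytest.raises((ValueError, AttributeError)):
            risk_point([1.0], [1.0], [1.0], None)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            RiskPoint(-0.1, 1.0)


class TestClassify:
    @pytest.mark.parametrize(
        "d_minus, d_plus, expected",
        [
            (2.0, 1.0, GROUP_POS),  # below the y = x line
            (1.0, 2.0, GROUP_NEG),  # above the line
            (1.0, 1.0, GROUP_POS),  # on-line tie is flagged risky
        ],
    )
    def test_y_equals_x_rule(self, d_minus, d_plus, expected):
        assert classify(RiskPoint(d_minus, d_plus)) == expected

    def test_matches_nearest_prototype_oracle(self):
        """On 1000 random fixtures the y = x rule agrees with brute-force
        nearest-prototype assignment in z-space (ties risky)."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = rng.integers(2, 8)
            scaler = PlanScaler(
                mean=rng.normal(size=p),
                sd=rng.uniform(0.5, 4.0, size=p),
                param_names=[f"x{i}" for i in range(p)],
            )
            plan, qm, qp = rng.normal(size=(3, p)) * 5
            pt = risk_point(plan, qm, qp, scaler)
            zp, zm, zq = (scaler.transform(v) for v in (plan, qm, qp))
            oracle = (
                GROUP_POS
                if np.linalg.norm(zp - zq) <= np.linalg.norm(zp - zm)
                else GROUP_NEG
            )
            assert classify(pt) == oracle

    def test_unit_rescaling_invariance(self):
        """Changing a parameter's unit (and refitting the scaler) moves no
        risk point by more than 1e-9."""
        rng = np.random.default_rng(7)
        plans = rng.normal(10, 2, size=(200, 6))
        qm = plans + rng.normal(0, 1, size=plans.shape)
        qp = plans + rng.normal(0, 1, size=plans.shape)
        scaler = PlanScaler(
            mean=plans.mean(0), sd=plans.std(0), param_names=PLAN_PARAMS
        )
        dm, dp = risk_points(plans, qm, qp, scaler)
        scale = np.ones(6)
        scale[2] = 1000.0  # e.g. grams -> milligrams
        scaled = plans * scale
        scaler2 = PlanScaler(
            mean=scaled.mean(0), sd=scaled.std(0), param_names=PLAN_PARAMS
        )
        dm2, dp2 = risk_points(scaled, qm * scale, qp * scale, scaler2)
        assert np.abs(dm - dm2).max() < 1e-9
        assert np.abs(dp - dp2).max() < 1e-9

    def test_parameter_permutation_invariance(self):
        rng = np.random.default_rng(8)
        plans, qm, qp = rng.normal(size=(3, 100, 6))
        scaler = _unit_scaler(6)
        dm, dp = risk_points(plans, qm, qp, scaler)
        perm = rng.permutation(6)
        dm2, dp2 = risk_points(plans[:, perm], qm[:, perm], qp[:, perm], scaler)
        assert np.abs(dm - dm2).max() < 1e-9
        assert np.abs(dp - dp2).max() < 1e-9


class TestComputeMetrics:
    def test_published_test_row_truncation(self):
        """TP=67, FP=17, FN=12, TN=54 reproduces the 0.797 / 0.848 / 0.806 /
        0.821 test-set row under truncation."""
        m = compute_metrics(67, 17, 12, 54, mode="truncate")
        assert m == {
            "precision": 0.797,
            "recall": 0.848,
            "accuracy": 0.806,
            "f1": 0.821,
        }

    def test_f1_from_rounded_precision_recall(self):
        # harmonic mean of already-3-decimal precision/recall
        f1 = compute_metrics(0, 0, 0, 1)["f1"]
        assert f1 == 0.0
        m = {"precision": 0.806, "recall": 0.785}
        harm = 2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"])
        assert np.floor(harm * 1000 + 1e-9) / 1000 == 0.795

    def test_degenerate_denominators(self):
        m = compute_metrics(0, 0, 0, 10)
        assert m == {"precision": 0.0, "recall": 0.0, "accuracy": 1.0, "f1": 0.0}

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(0, 0, 0, 0)

    @settings(derandomize=True, max_examples=200)
    @given(
        tp=st.integers(0, 500), fp=st.integers(0, 500),
        fn=st.integers(0, 500), tn=st.integers(0, 500),
        mode=st.sampled_from(["truncate", "round"]),
    )
    def test_metric_identities(self, tp, fp, fn, tn, mode):
        if tp + fp + fn + tn == 0:
            return
        m = compute_metrics(tp, fp, fn, tn, mode=mode)
        assert all(0.0 <= v <= 1.0 for v in m.values())
        assert m["accuracy"] == pytest.approx(
            np.floor((tp + tn) / (tp + fp + fn + tn) * 1000 + 1e-9) / 1000
            if mode == "truncate"
            else round((tp + tn) / (tp + fp + fn + tn), 3)
        )


class TestKmeansTreatments:
    def test_k1_center_is_mean(self, plan_frame):
        rng = np.random.default_rng(0)
        plans = plan_frame(np.abs(rng.normal(100, 10, size=(50, 6))) + 1)
        plans["AnesthesiaTime"] += 200  # keep cpb <= anesthesia plausible
        clusters = kmeans_treatments(plans, strata=[GROUP_NEG] * 50, k=1, seed=0)
        assert len(clusters) == 1
        for p in PLAN_PARAMS:
            assert clusters[0].center[p] == pytest.approx(plans[p].mean())

    def test_planted_blobs_recovered(self, plan_frame):
        """Three 6-D blobs with unit SD and centers >= 6 SD apart are
        recovered within 0.5 SD."""
        rng = np.random.default_rng(3)
        centers = np.array([[0.0] * 6, [8.0] * 6, [16.0] * 6]) + 100
        X = np.vstack([rng.normal(c, 1.0, size=(80, 6)) for c in centers])
        strata = [GROUP_NEG] * 160 + [GROUP_POS] * 80
        clusters = kmeans_treatments(plan_frame(X), strata=strata, k=3, seed=1)
        found = np.array(
            sorted([[c.center[p] for p in PLAN_PARAMS] for c in clusters],
                   key=lambda r: r[0])
        )
        assert np.abs(found - centers).max() < 0.5

    def test_majority_stratum_labels(self, plan_frame):
        rng = np.random.default_rng(3)
        X = np.vstack([
            rng.normal(100, 1.0, size=(40, 6)),
            rng.normal(120, 1.0, size=(40, 6)),
        ])
        strata = [GROUP_NEG] * 40 + [GROUP_POS] * 40
        clusters = kmeans_treatments(plan_frame(X), strata=strata, k=2, seed=0)
        assert sorted(c.label for c in clusters) == ["high-risk", "low-risk"]
        assert all(c.member_count == 40 for c in clusters)

    def test_too_few_distinct_plans_rejected(self, plan_frame):
        X = np.tile([300.0, 100.0, 40.0, 1.5, 1.0, 0.0], (10, 1))
        with pytest.raises(ValueError):
            kmeans_treatments(plan_frame(X), strata=[GROUP_NEG] * 10, k=3, seed=0)

    def test_default_cohort_yields_three_complete_centers(self, default_cohort):
        clusters = kmeans_treatments(
            default_cohort[PLAN_PARAMS], strata=default_cohort.Group, k=3, seed=2
        )
        assert len(clusters) == 3
        for c in clusters:
            assert set(c.center) == set(PLAN_PARAMS)
            assert set(c.ranges) == set(PLAN_PARAMS)


class TestMajorityVote:
    @pytest.mark.parametrize(
        "votes, winner, tie",
        [
            (("A", "A", "B"), "A", False),
            (("C", "C", "C"), "C", False),
            (("A", "B", "C"), "A", True),  # three-way tie -> first rater
        ],
    )
    def test_vote_outcomes(self, votes, winner, tie):
        assert majority_vote(votes) == (winner, tie)

    def test_empty_votes_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])


class TestRecommendGeometry:
    def test_hand_ordered_candidates(self):
        """Margins of three hand-placed plans on the 2-parameter toy sort
        exactly as computed by hand."""
        s = _unit_scaler(2)
        qm, qp = np.array([103.0, 1.0]), np.array([100.0, 5.0])
        plans = {
            "at_minus": [103.0, 1.0],  # margin = d_plus = 5.0
            "mid": [101.5, 3.0],       # equidistant, margin 0
            "at_plus": [100.0, 5.0],   # margin = -5.0
        }
        margins = {
            k: risk_point(v, qm, qp, s).margin for k, v in plans.items()
        }
        assert margins["at_minus"] == pytest.approx(5.0)
        assert margins["mid"] == pytest.approx(0.0)
        assert margins["at_plus"] == pytest.approx(-5.0)
        ordered = sorted(margins, key=margins.get, reverse=True)
        assert ordered == ["at_minus", "mid", "at_plus"]


class TestPlanShift:
    def test_identity_never_improves(self, pipeline_result):
        from akiplanner import plan_shift

        res = pipeline_result
        x = res.cohort[list(res.model_minus.feature_names)].iloc[5].to_numpy()
        before = res.cohort[PLAN_PARAMS].iloc[5].to_numpy()
        r1, r2, improved = plan_shift(
            x, before, before, res.model_minus, res.model_plus, res.plan_scaler
        )
        assert (r1.d_minus, r1.d_plus) == (r2.d_minus, r2.d_plus)
        assert improved is False

    def test_moving_to_low_risk_prototype_improves(self, pipeline_result):
        from akiplanner import plan_shift

        res = pipeline_result
        x = res.cohort[list(res.model_minus.feature_names)].iloc[5].to_numpy()
        before = res.cohort[PLAN_PARAMS].iloc[5].to_numpy()
        proposal = res.model_minus.predict(x)
        r1, r2, improved = plan_shift(
            x, before, proposal, res.model_minus, res.model_plus, res.plan_scaler
        )
        assert r2.d_minus == pytest.approx(0.0, abs=1e-9)
        # moving onto the low-risk prototype attains the maximal margin, so
        # it improves whenever the administered plan was off-prototype
        assert improved == (r2.margin > r1.margin)
        if r1.d_minus > 1e-6 and r1.margin < r2.margin:
            assert improved

    def test_moving_to_high_risk_prototype_lands_below_line(self, pipeline_result):
        from akiplanner import plan_shift

        res = pipeline_result
        x = res.cohort[list(res.model_minus.feature_names)].iloc[5].to_numpy()
        before = res.model_minus.predict(x)  # start on the low-risk prototype
        proposal = res.model_plus.predict(x)
        _, r2, improved = plan_shift(
            x, before, proposal, res.model_minus, res.model_plus, res.plan_scaler
        )
        assert r2.d_plus == pytest.approx(0.0, abs=1e-9)
        assert r2.d_plus <= r2.d_minus  # below the y = x line
        assert improved is False


class TestRecommendFullModel:
    def test_planner_proposal_ranks_low_risk(self, pipeline_result):
        res = pipeline_result
        x = res.cohort[list(res.model_minus.feature_names)].iloc[0].to_numpy()
        ranked = recommend(
            x, res.model_minus, res.model_plus, res.plan_scaler,
            seed=0, n_candidates=300,
        )
        # the AKI- Planner's own proposal: d_minus = 0, margin = d_plus >= 0
        top = ranked.iloc[0]
        assert top["d_minus"] == pytest.approx(0.0, abs=1e-9)
        assert top["margin"] >= 0
        assert top["risk_tag"] == "low-risk"
        assert (ranked["margin"].to_numpy()[:-1] >= ranked["margin"].to_numpy()[1:]).all()

    def test_aki_plus_prototype_is_high_risk(self, pipeline_result):
        res = pipeline_result
        x = res.cohort[list(res.model_minus.feature_names)].iloc[3].to_numpy()
        proto_p = res.model_plus.predict(x)
        pm = res.model_minus.predict(x)
        pt = risk_point(proto_p, pm, proto_p, res.plan_scaler)
        assert pt.d_plus == pytest.approx(0.0, abs=1e-9)
        assert pt.margin <= 0
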