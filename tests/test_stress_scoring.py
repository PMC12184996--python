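"""Per-feature scoring, weighted aggregation, status bands, ablation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stressface import (
    AppConfig,
    FeatureWeights,
    ScoreCalibration,
    ablation_analysis,
    aggregate_score,
    feature_score,
    score_session,
    status,
)
from stressface.facial_metrics import WindowMetrics
from stressface.landmarks import FEATURES, Feature

CAL = ScoreCalibration()


def metrics_with(**kw):
    m = WindowMetrics(start_frame=0, end_frame=60)
    for k, v in kw.items():
        setattr(m, k, v)
    return m


class TestFeatureScore:
    def test_open_eye_scores_zero(self):
        m = metrics_with(rel_aperture_left=1.0, squint_fraction_left=0.0)
        assert feature_score(m, Feature.EYE_LEFT, CAL) == 0.0

    def test_full_squint_window_scores_ten(self):
        m = metrics_with(rel_aperture_left=0.2, squint_fraction_left=1.0)
        assert feature_score(m, Feature.EYE_LEFT, CAL) == 10.0

    def test_nose_score_at_and_between_knots(self):
        # at the middle knot (0.12 -> 10), and linear between (0.12,10)-(0.4,0)
        m = metrics_with(nose_activity_index=0.12)
        assert feature_score(m, Feature.NOSE, CAL) == pytest.approx(10.0)
        m = metrics_with(nose_activity_index=0.26)
        expected = 10.0 * (0.4 - 0.26) / (0.4 - 0.12)  # hand evaluation
        assert feature_score(m, Feature.NOSE, CAL) == pytest.approx(expected)

    def test_ear_fold_and_asymmetry_bumps(self):
        base = metrics_with(ear_activity_left=0.13, ear_asymmetry=0.0)
        folded = metrics_with(ear_activity_left=0.13, ear_fold_left=True, ear_asymmetry=0.0)
        asym = metrics_with(ear_activity_left=0.13, ear_asymmetry=0.5)
        s0 = feature_score(base, Feature.EAR_LEFT, CAL)
        assert feature_score(folded, Feature.EAR_LEFT, CAL) == pytest.approx(
            min(10.0, s0 + CAL.fold_bump)
        )
        assert feature_score(asym, Feature.EAR_LEFT, CAL) == pytest.approx(
            min(10.0, s0 + 0.5 * CAL.asymmetry_gain)
        )

    def test_missing_landmarks_give_missing_score(self):
        m = metrics_with()  # all drivers NaN
        assert np.isnan(feature_score(m, Feature.NOSE, CAL))
        assert np.isnan(feature_score(m, Feature.EYE_RIGHT, CAL))

    def test_scores_clamped_to_scale(self):
        m = metrics_with(ear_activity_left=0.0, ear_fold_left=True, ear_asymmetry=1.0)
        assert feature_score(m, Feature.EAR_LEFT, CAL) == 10.0


class TestAggregate:
    def test_equal_scores(self):
        scores = {f: 5.0 for f in FEATURES}
        assert aggregate_score(scores, FeatureWeights()) == 5.0

    def test_single_high_score(self):
        scores = dict(zip(FEATURES, [10.0, 0.0, 0.0, 0.0, 0.0]))
        assert aggregate_score(scores, FeatureWeights()) == pytest.approx(2.0)

    def test_hand_computed_weighted_mean(self):
        scores = dict(zip(FEATURES, [8.0, 2.0, 4.0, 6.0, 0.0]))
        w = dict(zip(FEATURES, [2.0, 1.0, 1.0, 1.0, 0.0]))
        expected = (2 * 8 + 1 * 2 + 1 * 4 + 1 * 6) / 5  # independent computation
        assert aggregate_score(scores, FeatureWeights(w)) == pytest.approx(expected)

    def test_all_weights_zero_on_scored_features_raises(self):
        scores = {Feature.NOSE: 5.0}
        w = FeatureWeights({f: (0.0 if f is Feature.NOSE else 1.0) for f in FEATURES})
        with pytest.raises(ValueError):
            aggregate_score(scores, w)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 10), min_size=5, max_size=5),
        st.lists(st.floats(0, 5), min_size=5, max_size=5),
    )
    def test_bounded_and_zero_weight_equals_deletion(self, scores, weights):
        if all(w == 0 for w in weights):
            weights = [1.0] * 5
        smap = dict(zip(FEATURES, scores))
        wmap = FeatureWeights(dict(zip(FEATURES, weights)))
        total = aggregate_score(smap, wmap)
        active = [s for s, w in zip(scores, weights) if w > 0]
        assert min(active) - 1e-12 <= total <= max(active) + 1e-12
        # zero weight == feature deleted from the input
        reduced = {f: s for f, s in smap.items() if wmap[f] > 0}
        assert aggregate_score(reduced, wmap) == total

    def test_monotone_in_any_single_score(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            scores = dict(zip(FEATURES, rng.uniform(0, 10, 5)))
            w = FeatureWeights(dict(zip(FEATURES, rng.uniform(0.1, 3, 5))))
            f = FEATURES[rng.integers(5)]
            bumped = dict(scores)
            bumped[f] = min(10.0, scores[f] + 1.0)
            assert aggregate_score(bumped, w) >= aggregate_score(scores, w)


class TestStatus:
    THR = (10.0 / 3.0, 20.0 / 3.0)

    @pytest.mark.parametrize(
        "total,expected",
        [(0.0, "okay"), (10.0, "stressed"), (10.0 / 3.0, "caution"), (5.0, "caution")],
    )
    def test_bands(self, total, expected):
        assert status(total, self.THR) == expected

    def test_invalid_threshold_order(self):
        with pytest.raises(ValueError):
            status(5.0, (7.0, 3.0))


class TestScoreSession:
    def test_relaxed_session_in_okay_band(self, relaxed_session, config):
        _, table = relaxed_session
        report = score_session(table, config=config)
        assert report.session_mean < config.status_thresholds[0]
        assert report.session_status == "okay"

    def test_stressed_session_in_stressed_band(self, stressed_session, config):
        _, table = stressed_session
        report = score_session(table, config=config)
        assert report.session_mean > config.status_thresholds[1]
        assert report.session_status == "stressed"

    def test_scale_and_translation_invariance(self, stressed_session, config):
        _, table = stressed_session
        base = score_session(table, config=config)
        for factor in (0.5, 3.0):
            moved = table.copy()
            moved.xy = moved.xy * factor + np.array([41.0, -13.0])
            other = score_session(moved, config=config)
            assert np.allclose(other.totals, base.totals, atol=1e-9, equal_nan=True)
            assert other.session_mean == pytest.approx(base.session_mean, abs=1e-9)

    def test_report_is_deterministic(self, relaxed_session, config):
        _, table = relaxed_session
        a = score_session(table, config=config).to_json()
        b = score_session(table, config=config).to_json()
        assert a == b

    def test_report_roundtrips_to_json(self, relaxed_session, config, tmp_path):
        import json

        _, table = relaxed_session
        report = score_session(table, config=config)
        report.to_json(tmp_path / "r.json")
        loaded = json.loads((tmp_path / "r.json").read_text())
        assert loaded["session_status"] == report.session_status
        assert len(loaded["windows"]) == len(report.windows)
        assert loaded["config_hash"] == config.config_hash()


class TestAblation:
    def test_empty_removal_is_zero(self, relaxed_session):
        _, table = relaxed_session
        result = ablation_analysis(table)
        assert result.deviations[()] == 0.0

    def test_removing_feature_equal_to_total_changes_nothing(self):
        # analytic case via the aggregation algebra on fixed scores
        scores = {f: 4.0 for f in FEATURES}
        w = FeatureWeights()
        base = aggregate_score(scores, w)
        assert aggregate_score(scores, w.without([Feature.NOSE])) == base

    def test_deviation_grows_with_removed_count(self, stressed_session):
        _, table = stressed_session
        result = ablation_analysis(table)
        sizes = sorted(result.by_size)
        assert sizes == [0, 1, 2, 3, 4]
        devs = [result.by_size[s] for s in sizes]
        assert all(b >= a - 1e-12 for a, b in zip(devs, devs[1:]))
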