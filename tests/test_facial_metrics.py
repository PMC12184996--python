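"""Window heuristics: apertures, squint epochs, motion indices, freezing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from stressface import WindowConfig
from stressface.facial_metrics import (
    activity_index,
    body_scale,
    compute_aperture_baseline,
    detect_freezing,
    detect_squint_epochs,
    ear_median_positions,
    ear_metrics,
    euclidean_distance,
    eye_aperture_series,
    max_range_of_motion,
    moving_average,
    travel_distance,
    windowed_metrics,
)
from stressface.landmarks import LANDMARK_INDEX

from conftest import still_table

WCFG = WindowConfig()


@pytest.mark.parametrize(
    "p1,p2,expected",
    [((0, 0), (3, 4), 5.0), ((1, 1), (1, 1), 0.0), ((0, 0), (1, 1), np.sqrt(2))],
)
def test_euclidean_distance_examples(p1, p2, expected):
    assert euclidean_distance(p1, p2) == pytest.approx(expected)


def test_euclidean_distance_propagates_missing():
    assert np.isnan(euclidean_distance((np.nan, 0), (1, 1)))


def test_aperture_series_constant_and_shape():
    table = still_table(n_frames=45)  # eyelids 20 px apart
    raw, smoothed = eye_aperture_series(table, "left")
    assert raw.shape == smoothed.shape == (45,)
    assert np.allclose(raw, 20.0) and np.allclose(smoothed, 20.0)


def test_smoothed_series_matches_brute_force_moving_average():
    fps = 30
    t = np.arange(150)
    table = still_table(n_frames=150, fps=fps)
    j = LANDMARK_INDEX["eyelid_lower_left"]
    table.xy[:, j, 1] = 540.0 + 6.0 * np.sin(2 * np.pi * t / 60)  # sinusoidal closure
    raw, smoothed = eye_aperture_series(table, "left")
    # centred moving average computed by explicit slicing over
    # [i - w//2, i + (w-1)//2], the documented window placement
    expected = np.array(
        [
            np.mean(raw[max(0, i - fps // 2) : i + (fps - 1) // 2 + 1])
            for i in range(len(raw))
        ]
    )
    assert np.allclose(smoothed, expected)


class TestBaseline:
    def test_constant(self):
        assert compute_aperture_baseline(np.full(50, 6.0)) == 6.0

    def test_brute_force_percentile(self):
        series = np.array([6.0] * 90 + [1.0] * 10)
        # independent oracle: sorted linear-interpolated 75th percentile
        s = np.sort(series)
        k = 0.75 * (len(s) - 1)
        expected = s[int(k)] + (k - int(k)) * (s[min(int(k) + 1, len(s) - 1)] - s[int(k)])
        assert compute_aperture_baseline(series) == expected == 6.0

    def test_scaling_homogeneity(self):
        rng = np.random.default_rng(0)
        series = rng.uniform(1, 20, 200)
        assert compute_aperture_baseline(3.5 * series) == pytest.approx(
            3.5 * compute_aperture_baseline(series)
        )

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            compute_aperture_baseline(np.full(5, np.nan))


class TestSquintEpochs:
    def make_trace(self, closure_frames, fps=30, baseline=20.0):
        ap = np.full(300, baseline)
        ap[100 : 100 + closure_frames] = 0.1 * baseline
        return ap

    @pytest.mark.parametrize(
        "seconds,kind",
        [(0.5, "blink"), (0.99, "blink"), (1.0, "squint"), (2.0, "squint")],
    )
    def test_blink_vs_squint_boundary(self, seconds, kind):
        fps = 30
        ap = self.make_trace(int(seconds * fps), fps)
        epochs = detect_squint_epochs(ap, fps, 20.0, WCFG)
        assert len(epochs) == 1
        assert epochs[0].kind == kind

    def test_open_eye_yields_no_epochs(self):
        assert detect_squint_epochs(np.full(100, 20.0), 30, 20.0, WCFG) == []

    def test_nonpositive_baseline_raises(self):
        with pytest.raises(ValueError):
            detect_squint_epochs(np.full(10, 5.0), 30, 0.0, WCFG)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(arrays(float, 200, elements=st.floats(0, 25)), st.integers(15, 60))
    def test_epochs_disjoint_ordered_and_kind_consistent(self, ap, fps):
        epochs = detect_squint_epochs(ap, fps, 20.0, WCFG)
        last_end = -1
        for e in epochs:
            assert e.start_frame > last_end
            assert e.duration_s == e.n_frames / fps
            assert (e.kind == "blink") == (e.duration_s < WCFG.blink_max_s)
            last_end = e.end_frame


class TestMotion:
    def test_stationary(self):
        pts = np.zeros((10, 2))
        assert max_range_of_motion(pts) == 0.0
        assert travel_distance(pts) == 0.0

    def test_two_point_diameter(self):
        assert max_range_of_motion([(0, 0), (3, 4)]) == 5.0

    def test_travel_unit_steps(self):
        assert travel_distance([(0, 0), (1, 0), (1, 1)]) == pytest.approx(2.0)

    def test_against_brute_force(self):
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 100, (50, 2))
        brute_max = max(
            np.hypot(*(pts[i] - pts[j]))
            for i in range(50)
            for j in range(i + 1, 50)
        )
        brute_travel = sum(np.hypot(*(pts[i + 1] - pts[i])) for i in range(49))
        assert max_range_of_motion(pts) == pytest.approx(brute_max, abs=1e-12)
        assert travel_distance(pts) == pytest.approx(brute_travel, abs=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(arrays(float, (30, 2), elements=st.floats(-1e3, 1e3)))
    def test_travel_dominates_range(self, pts):
        assert travel_distance(pts) >= max_range_of_motion(pts) - 1e-9

    def test_missing_frames_bridged(self):
        pts = np.array([(0.0, 0.0), (np.nan, np.nan), (2.0, 0.0)])
        assert travel_distance(pts) == pytest.approx(2.0)

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            max_range_of_motion(np.full((3, 2), np.nan))


class TestActivityIndex:
    def test_examples(self):
        assert activity_index(0, 0, 10) == 0.0
        assert activity_index(5, 5, 10) == pytest.approx(0.5)

    def test_homogeneity(self):
        assert activity_index(3, 7, 11) == pytest.approx(activity_index(6, 14, 22))

    def test_bad_scale(self):
        with pytest.raises(ValueError):
            activity_index(1, 1, 0)


class TestEarMetrics:
    def test_identical_ears_symmetric(self):
        table = still_table()
        rng = np.random.default_rng(3)
        wiggle = rng.normal(0, 2, (60, 2))
        for name in ("ear_left", "ear_right"):
            table.xy[:, LANDMARK_INDEX[name]] += wiggle
        aL, aR, asym, foldL, foldR = ear_metrics(table, (0, 60), WCFG)
        assert aL == pytest.approx(aR)
        assert asym == pytest.approx(0.0)
        assert foldL is False and foldR is False

    def test_one_still_ear_full_asymmetry_no_fold(self):
        table = still_table()
        rng = np.random.default_rng(4)
        table.xy[:, LANDMARK_INDEX["ear_right"]] += rng.normal(0, 2, (60, 2))
        # left ear frozen exactly at its median position: still but not displaced
        aL, aR, asym, foldL, _ = ear_metrics(table, (0, 60), WCFG)
        assert aL == 0.0 and aR > 0
        assert asym == pytest.approx(1.0)
        assert foldL is False

    def test_pinned_displaced_ear_is_fold(self):
        table = still_table(n_frames=120)
        j = LANDMARK_INDEX["ear_left"]
        scale = body_scale(table)
        medians = ear_median_positions(table)
        table.xy[60:, j] += 0.3 * scale  # pinned, displaced, motionless
        cfg = WindowConfig(fold_range_threshold=0.02, fold_displacement_threshold=0.1)
        # hand evaluation: range 0 < 0.02*scale; displacement 0.3*scale*sqrt(2) > 0.1*scale
        _, _, _, foldL, foldR = ear_metrics(
            table, (60, 120), cfg, scale=scale, ear_medians=medians
        )
        assert foldL is True and foldR is False

    def test_both_ears_still_is_symmetric(self):
        table = still_table()
        aL, aR, asym, *_ = ear_metrics(table, (0, 60), WCFG)
        assert aL == aR == 0.0 and asym == 0.0


class TestWindowing:
    def test_window_count_10s(self):
        table = still_table(n_frames=300)  # 10 s at 30 fps
        assert len(windowed_metrics(table, WCFG)) == 5

    def test_partial_window_kept_when_half_full(self):
        table = still_table(n_frames=330)  # 11 s: 5 full + one half window
        ms = windowed_metrics(table, WCFG)
        assert len(ms) == 6
        assert ms[-1].valid_fraction == pytest.approx(0.5)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            windowed_metrics(still_table(n_frames=20), WCFG)

    def test_travel_dominates_range_in_every_window(self, relaxed_session):
        _, table = relaxed_session
        for m in windowed_metrics(table, WCFG):
            assert m.nose_travel >= m.nose_max_range - 1e-9
            assert m.nose_max_range >= 0

    def test_concatenation_consistency(self, relaxed_session):
        """Windowing two aligned halves with fixed session context equals
        windowing the whole table."""
        _, table = relaxed_session
        scale = body_scale(table)
        medians = ear_median_positions(table)
        raw_l, _ = eye_aperture_series(table, "left")
        raw_r, _ = eye_aperture_series(table, "right")
        baselines = {
            "left": compute_aperture_baseline(raw_l),
            "right": compute_aperture_baseline(raw_r),
        }
        kw = dict(scale=scale, baselines=baselines, ear_medians=medians)
        whole = windowed_metrics(table, WCFG, **kw)
        split = 300  # aligned to the 60-frame window grid
        parts = windowed_metrics(table.slice(0, split), WCFG, **kw) + windowed_metrics(
            table.slice(split, table.n_frames), WCFG, **kw
        )
        assert len(whole) == len(parts)
        for a, b in zip(whole, parts):
            for attr in ("nose_activity_index", "ear_activity_left", "ear_asymmetry"):
                va, vb = getattr(a, attr), getattr(b, attr)
                assert va == pytest.approx(vb, nan_ok=True)


class TestFreezing:
    def test_still_windows_freeze(self):
        ms = windowed_metrics(still_table(n_frames=300), WCFG)
        assert detect_freezing(ms, WCFG) == [True] * 5

    def test_vigorous_motion_never_freezes(self, relaxed_session):
        _, table = relaxed_session
        ms = windowed_metrics(table, WCFG)
        assert detect_freezing(ms, WCFG) == [False] * len(ms)

    def test_alternating_pattern_matches_construction(self):
        from stressface.session_simulator import SimulationConfig, simulate_session
        from stressface import CleaningConfig, clean_trajectories

        schedule = [("relaxed", 4.0), ("stressed_freeze", 4.0)] * 2
        sim = simulate_session(SimulationConfig(seed=5, duration_s=16.0, state_schedule=schedule))
        table = clean_trajectories(sim.table, CleaningConfig())
        ms = windowed_metrics(table, WCFG)
        # 2 s windows: frames 0-120 relaxed, 120-240 frozen, repeating
        expected = [False, False, True, True] * 2
        assert [m.freezing for m in ms] == expected


def test_metrics_invariant_under_rescale_and_translation(relaxed_session):
    _, table = relaxed_session
    ms0 = windowed_metrics(table, WCFG)
    moved = table.copy()
    moved.xy = moved.xy * 2.0 + np.array([123.0, -77.0])
    ms1 = windowed_metrics(moved, WCFG)
    for a, b in zip(ms0, ms1):
        assert b.nose_activity_index == pytest.approx(a.nose_activity_index, abs=1e-9)
        assert b.ear_activity_left == pytest.approx(a.ear_activity_left, abs=1e-9)
        assert b.ear_asymmetry == pytest.approx(a.ear_asymmetry, abs=1e-9, nan_ok=True)
        assert b.rel_aperture_left == pytest.approx(a.rel_aperture_left, abs=1e-9)
        assert (b.ear_fold_left, b.freezing) == (a.ear_fold_left, a.freezing)
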