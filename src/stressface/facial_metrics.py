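"""Per-window heuristic quantities computed on cleaned landmark trajectories.

The heuristics quantify the facial correlates of stress in a head-fixed
mouse: sustained eye closure (squinting, as opposed to sub-second
blinking), reduced nose and ear motion (freezing), left/right ear
asymmetry, and an ear held immobile away from its resting position
(fold).  All motion quantities are normalised by a body scale (median
inter-ear distance by default) so they are camera-distance invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .config import WindowConfig
from .keypoint_io import TrajectoryTable
from .landmarks import EARS, EYELID_PAIRS, Landmark


def euclidean_distance(p1, p2) -> float | np.ndarray:
    """Euclidean distance between two points (or arrays of points).

    NaN coordinates propagate to a NaN distance.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    return np.hypot(p1[..., 0] - p2[..., 0], p1[..., 1] - p2[..., 1])


def eye_aperture_series(
    table: TrajectoryTable, eye: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame eyelid aperture for one eye.

    Returns ``(raw, smoothed)``: the raw upper-to-lower eyelid distance per
    frame, and a centred moving average over one second (``round(fps)``
    frames) of the distance series.  Frames with a missing eyelid give a
    missing (NaN) aperture.
    """
    upper, lower = EYELID_PAIRS[eye]
    raw = euclidean_distance(table.landmark_xy(upper), table.landmark_xy(lower))
    smoothed = moving_average(raw, max(1, round(table.fps)))
    return raw, smoothed


def moving_average(series: np.ndarray, window: int) -> np.ndarray:
    """Centred NaN-aware moving average with min_periods=1.

    The window at index i covers [i - window//2, i + (window-1)//2],
    truncated at the series edges.
    """
    import pandas as pd

    return (
        pd.Series(np.asarray(series, dtype=float))
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def compute_aperture_baseline(aperture: np.ndarray) -> float:
    """Robust open-eye reference aperture: 75th percentile of the series."""
    aperture = np.asarray(aperture, dtype=float)
    if aperture.size == 0 or np.all(np.isnan(aperture)):
        raise ValueError("aperture series has no non-missing values")
    return float(np.nanpercentile(aperture, 75))


@dataclass(frozen=True)
class SquintEpoch:
    """A maximal run of closed-eye frames, classified blink vs squint."""

    start_frame: int
    end_frame: int  # inclusive
    duration_s: float
    kind: str  # "blink" | "squint"
    eye: str  # "left" | "right"

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def detect_squint_epochs(
    aperture: np.ndarray,
    fps: float,
    baseline: float,
    config: WindowConfig,
    eye: str = "left",
) -> list[SquintEpoch]:
    """Find maximal closed-eye runs and classify them blink vs squint.

    A frame is closed when its aperture is below
    ``closure_fraction * baseline`` (missing frames count as open).
    Epochs strictly shorter than ``blink_max_s`` are blinks; the rest are
    squints, the only kind that contributes to stress.
    """
    if not baseline > 0:
        raise ValueError("baseline must be > 0")
    aperture = np.asarray(aperture, dtype=float)
    with np.errstate(invalid="ignore"):
        closed = aperture < config.closure_fraction * baseline
    epochs: list[SquintEpoch] = []
    if not closed.any():
        return epochs
    idx = np.flatnonzero(closed)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in runs:
        duration = len(run) / fps
        kind = "blink" if duration < config.blink_max_s else "squint"
        epochs.append(
            SquintEpoch(int(run[0]), int(run[-1]), duration, kind, eye)
        )
    return epochs


def _valid_points(positions) -> np.ndarray:
    pos = np.asarray(positions, dtype=float)
    return pos[~np.isnan(pos).any(axis=1)]


def max_range_of_motion(positions) -> float:
    """Largest displacement within a window: the max pairwise distance.

    Implemented as the diameter of the point set so the result does not
    depend on which frame the window happens to start on.
    """
    pos = _valid_points(positions)
    if len(pos) == 0:
        raise ValueError("window contains no non-missing positions")
    if len(pos) == 1:
        return 0.0
    return float(pdist(pos).max())


def travel_distance(positions) -> float:
    """Cumulative distance between consecutive (non-missing) positions.

    Missing frames are skipped; the gap is bridged by a single segment.
    """
    pos = _valid_points(positions)
    if len(pos) == 0:
        raise ValueError("window contains no non-missing positions")
    if len(pos) == 1:
        return 0.0
    return float(np.hypot(*np.diff(pos, axis=0).T).sum())


def activity_index(max_range: float, travel: float, scale: float) -> float:
    """Unitless activity: mean of the scale-normalised range and travel."""
    if not scale > 0:
        raise ValueError("scale must be > 0")
    return (max_range / scale + travel / scale) / 2.0


def body_scale(table: TrajectoryTable) -> float:
    """Normalising body scale: median inter-ear distance over the session."""
    d = euclidean_distance(
        table.landmark_xy(Landmark.EAR_LEFT), table.landmark_xy(Landmark.EAR_RIGHT)
    )
    if np.all(np.isnan(d)):
        raise ValueError("cannot determine body scale: ears never jointly visible")
    return float(np.nanmedian(d))


def ear_median_positions(table: TrajectoryTable) -> dict[str, np.ndarray]:
    """Per-ear session-median (x, y); reference for fold displacement."""
    out = {}
    for side, lm in EARS.items():
        pos = table.landmark_xy(lm)
        out[side] = (
            np.array([np.nan, np.nan])
            if np.all(np.isnan(pos))
            else np.nanmedian(pos, axis=0)
        )
    return out


def ear_metrics(
    table: TrajectoryTable,
    window: tuple[int, int],
    config: WindowConfig,
    scale: float | None = None,
    ear_medians: dict[str, np.ndarray] | None = None,
) -> tuple[float, float, float, bool | None, bool | None]:
    """Ear activity, asymmetry and fold flags for one frame window.

    Returns ``(activity_left, activity_right, asymmetry, fold_left,
    fold_right)``.  Asymmetry is ``|aL - aR| / (aL + aR)`` with 0 when both
    activities are 0 (two still ears are symmetric).  An ear is folded when
    it is both immobile (max range below ``fold_range_threshold * scale``)
    and displaced (window-mean position further than
    ``fold_displacement_threshold * scale`` from its session median).
    Fully-missing ears yield NaN activity and ``None`` fold flags.
    """
    if scale is None:
        scale = body_scale(table)
    if ear_medians is None:
        ear_medians = ear_median_positions(table)
    start, stop = window
    act: dict[str, float] = {}
    fold: dict[str, bool | None] = {}
    for side, lm in EARS.items():
        pos = table.landmark_xy(lm)[start:stop]
        valid = _valid_points(pos)
        if len(valid) == 0:
            act[side] = float("nan")
            fold[side] = None
            continue
        rng = max_range_of_motion(valid)
        act[side] = activity_index(rng, travel_distance(valid), scale)
        median = ear_medians[side]
        if np.any(np.isnan(median)):
            fold[side] = None
        else:
            displacement = float(euclidean_distance(valid.mean(axis=0), median))
            fold[side] = bool(
                rng < config.fold_range_threshold * scale
                and displacement > config.fold_displacement_threshold * scale
            )
    aL, aR = act["left"], act["right"]
    if np.isnan(aL) or np.isnan(aR):
        asym = float("nan")
    elif aL + aR == 0:
        asym = 0.0
    else:
        asym = abs(aL - aR) / (aL + aR)
    return aL, aR, asym, fold["left"], fold["right"]


@dataclass
class WindowMetrics:
    """All heuristic quantities for one evaluation window."""

    start_frame: int
    end_frame: int  # exclusive
    aperture_left: float = float("nan")
    aperture_right: float = float("nan")
    rel_aperture_left: float = float("nan")
    rel_aperture_right: float = float("nan")
    squint_fraction_left: float = float("nan")
    squint_fraction_right: float = float("nan")
    nose_max_range: float = float("nan")
    nose_travel: float = float("nan")
    nose_activity_index: float = float("nan")
    ear_activity_left: float = float("nan")
    ear_activity_right: float = float("nan")
    ear_asymmetry: float = float("nan")
    ear_fold_left: bool | None = None
    ear_fold_right: bool | None = None
    freezing: bool = False
    valid_fraction: float = 0.0


def detect_freezing(
    metrics: Sequence[WindowMetrics], config: WindowConfig
) -> list[bool]:
    """Freezing flags: nose and both ear activities all below threshold."""
    thr = config.freeze_activity_threshold
    out = []
    for m in metrics:
        vals = (m.nose_activity_index, m.ear_activity_left, m.ear_activity_right)
        out.append(bool(all(not np.isnan(v) and v < thr for v in vals)))
    return out


def _squint_coverage(epochs: list[SquintEpoch], start: int, stop: int) -> float:
    """Fraction of [start, stop) covered by squint-kind epochs."""
    covered = 0
    for e in epochs:
        if e.kind != "squint":
            continue
        covered += max(0, min(stop - 1, e.end_frame) - max(start, e.start_frame) + 1)
    return covered / max(1, stop - start)


def windowed_metrics(
    table: TrajectoryTable,
    config: WindowConfig,
    *,
    scale: float | None = None,
    baselines: dict[str, float] | None = None,
    ear_medians: dict[str, np.ndarray] | None = None,
) -> list[WindowMetrics]:
    """Assemble :class:`WindowMetrics` over consecutive tumbling windows.

    Windows are non-overlapping spans of ``window_s`` seconds; a trailing
    partial window is kept when at least half full and is down-weighted via
    ``valid_fraction`` (whose denominator is always the full window
    length).  Session-level context (body scale, per-eye aperture
    baselines, ear median positions) is computed from the table unless
    passed explicitly — the live monitor passes rolling equivalents.
    """
    win_n = round(config.window_s * table.fps)
    n = table.n_frames
    if n < 0.5 * win_n:
        raise ValueError("table shorter than half a window")
    if scale is None:
        scale = body_scale(table)
    if ear_medians is None:
        ear_medians = ear_median_positions(table)

    apertures: dict[str, np.ndarray] = {}
    epochs: dict[str, list[SquintEpoch]] = {}
    eye_baselines: dict[str, float] = {}
    for side in ("left", "right"):
        raw, _ = eye_aperture_series(table, side)
        apertures[side] = raw
        if baselines is not None and side in baselines:
            b = baselines[side]
        else:
            try:
                b = compute_aperture_baseline(raw)
            except ValueError:
                b = float("nan")
        eye_baselines[side] = b
        epochs[side] = (
            detect_squint_epochs(raw, table.fps, b, config, eye=side)
            if b > 0
            else []
        )

    starts = list(range(0, n, win_n))
    if starts and n - starts[-1] < 0.5 * win_n:
        starts.pop()  # trailing remnant under half a window: merged away

    nose = table.landmark_xy(Landmark.NOSE)
    all_present = ~np.isnan(table.xy).any(axis=(1, 2))
    out: list[WindowMetrics] = []
    for s in starts:
        e = min(s + win_n, n)
        m = WindowMetrics(start_frame=s, end_frame=e)
        m.valid_fraction = float(all_present[s:e].sum()) / win_n
        for side in ("left", "right"):
            ap = apertures[side][s:e]
            mean_ap = float(np.nanmean(ap)) if not np.all(np.isnan(ap)) else float("nan")
            setattr(m, f"aperture_{side}", mean_ap)
            b = eye_baselines[side]
            setattr(
                m,
                f"rel_aperture_{side}",
                mean_ap / b if b and b > 0 else float("nan"),
            )
            setattr(m, f"squint_fraction_{side}", _squint_coverage(epochs[side], s, e))
        npos = _valid_points(nose[s:e])
        if len(npos):
            m.nose_max_range = max_range_of_motion(npos)
            m.nose_travel = travel_distance(npos)
            m.nose_activity_index = activity_index(m.nose_max_range, m.nose_travel, scale)
        (
            m.ear_activity_left,
            m.ear_activity_right,
            m.ear_asymmetry,
            m.ear_fold_left,
            m.ear_fold_right,
        ) = ear_metrics(table, (s, e), config, scale=scale, ear_medians=ear_medians)
        out.append(m)

    for m, frozen in zip(out, detect_freezing(out, config)):
        m.freezing = frozen
    return out
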