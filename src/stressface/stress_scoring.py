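"""Map window metrics to 0-10 per-feature scores, aggregate, classify.

Each of the five composite features (two eyes, two ears, nose) gets a
piecewise-linear score on 0-10 from its driving metrics; the weighted mean
of the feature scores is the window's total stress level, and two cut
points turn the total into a 3-level status (okay / caution / stressed).
Setting a feature's weight to zero is exactly equivalent to deleting it,
which is what the ablation analysis exploits.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AppConfig, FeatureWeights, ScoreCalibration
from .facial_metrics import WindowMetrics, body_scale, windowed_metrics
from .keypoint_io import TrajectoryTable
from .landmarks import FEATURES, Feature

OKAY, CAUTION, STRESSED = "okay", "caution", "stressed"


def _pl(knots, x: float) -> float:
    """Piecewise-linear evaluation with constant extrapolation."""
    xs = np.array([k[0] for k in knots])
    ys = np.array([k[1] for k in knots])
    return float(np.interp(x, xs, ys))


def _clamp(x: float) -> float:
    return float(min(10.0, max(0.0, x)))


def feature_score(
    metrics: WindowMetrics, feature: Feature, calibration: ScoreCalibration
) -> float:
    """Score one feature on 0-10 for one window; NaN when its landmarks
    were missing throughout the window.

    Eyes: squint-coverage term plus a low-aperture term.  Nose: inverted
    activity (immobility scores high).  Ears: inverted activity plus fixed
    bumps for a detected fold and for asymmetry.
    """
    feature = Feature(feature)
    if feature is Feature.NOSE:
        a = metrics.nose_activity_index
        if np.isnan(a):
            return float("nan")
        return _clamp(_pl(calibration.nose_activity_knots, a))
    if feature in (Feature.EYE_LEFT, Feature.EYE_RIGHT):
        side = "left" if feature is Feature.EYE_LEFT else "right"
        rel = getattr(metrics, f"rel_aperture_{side}")
        if np.isnan(rel):
            return float("nan")
        sf = getattr(metrics, f"squint_fraction_{side}")
        return _clamp(
            _pl(calibration.eye_squint_knots, sf)
            + _pl(calibration.eye_aperture_knots, rel)
        )
    side = "left" if feature is Feature.EAR_LEFT else "right"
    a = getattr(metrics, f"ear_activity_{side}")
    if np.isnan(a):
        return float("nan")
    score = _pl(calibration.ear_activity_knots, a)
    if getattr(metrics, f"ear_fold_{side}"):
        score += calibration.fold_bump
    asym = metrics.ear_asymmetry
    if not np.isnan(asym):
        score += calibration.asymmetry_gain * asym
    return _clamp(score)


def aggregate_score(
    scores: Mapping[Feature, float], weights: FeatureWeights
) -> float:
    """Weighted mean over features with positive weight and a non-missing
    score; bounded by the min and max of the contributing scores."""
    num = den = 0.0
    for f in FEATURES:
        w = weights[f]
        s = scores.get(f, float("nan"))
        if w > 0 and not np.isnan(s):
            num += w * s
            den += w
    if den == 0:
        raise ValueError("no feature with positive weight and non-missing score")
    return num / den


def status(total: float, thresholds: tuple[float, float]) -> str:
    """3-level status: okay below t_caution, stressed at/above t_stressed."""
    t_caution, t_stressed = thresholds
    if not 0.0 <= t_caution < t_stressed <= 10.0:
        raise ValueError("invalid status thresholds")
    if total < t_caution:
        return OKAY
    if total < t_stressed:
        return CAUTION
    return STRESSED


@dataclass
class WindowScore:
    """Scores and status for one window."""

    start_frame: int
    end_frame: int
    scores: dict[Feature, float]
    total: float
    status: str
    valid_fraction: float
    metrics: WindowMetrics


@dataclass
class StressReport:
    """Full per-session scoring output."""

    windows: list[WindowScore]
    session_mean: float
    session_status: str
    weights: FeatureWeights
    config_hash: str
    fps: float
    source: str = ""
    schema_version: int = 1

    @property
    def totals(self) -> np.ndarray:
        return np.array([w.total for w in self.windows])

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "config_hash": self.config_hash,
            "fps": self.fps,
            "source": self.source,
            "weights": {f.value: v for f, v in self.weights.weights.items()},
            "session_mean": self.session_mean,
            "session_status": self.session_status,
            "windows": [
                {
                    "start_frame": w.start_frame,
                    "end_frame": w.end_frame,
                    "total": w.total,
                    "status": w.status,
                    "valid_fraction": w.valid_fraction,
                    "scores": {f.value: s for f, s in w.scores.items()},
                }
                for w in self.windows
            ],
        }

    def to_json(self, path=None) -> str:
        def _default(o):
            if isinstance(o, float) and np.isnan(o):
                return None
            return float(o)

        text = json.dumps(self.to_dict(), indent=2, default=_default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def windows_dataframe(self) -> pd.DataFrame:
        """Tidy one-row-per-window table (metrics + scores) for export."""
        rows = []
        for w in self.windows:
            row = dict(vars(w.metrics))
            row.update({f"score_{f.value}": s for f, s in w.scores.items()})
            row["total"] = w.total
            row["status"] = w.status
            rows.append(row)
        return pd.DataFrame(rows)


def window_scores(
    metrics: Sequence[WindowMetrics],
    weights: FeatureWeights,
    calibration: ScoreCalibration,
    thresholds: tuple[float, float],
) -> list[WindowScore]:
    out = []
    for m in metrics:
        scores = {f: feature_score(m, f, calibration) for f in FEATURES}
        try:
            total = aggregate_score(scores, weights)
            st = status(total, thresholds)
        except ValueError:  # every effective feature missing in this window
            total, st = float("nan"), "missing"
        out.append(
            WindowScore(
                m.start_frame, m.end_frame, scores, total, st, m.valid_fraction, m
            )
        )
    return out


def _session_scale(table: TrajectoryTable, calibration: ScoreCalibration) -> float:
    if calibration.scale_definition == "config_constant":
        return calibration.scale_constant
    return body_scale(table)


def score_session(
    table: TrajectoryTable,
    weights: FeatureWeights | None = None,
    calibration: ScoreCalibration | None = None,
    config: AppConfig | None = None,
) -> StressReport:
    """Score a cleaned session table window by window.

    The session mean is the mean of window totals weighted by each
    window's ``valid_fraction``, so partial or dropout-ridden windows
    count less.
    """
    config = config or AppConfig(fps=table.fps)
    weights = weights or config.weights
    calibration = calibration or config.calibration
    metrics = windowed_metrics(
        table, config.window, scale=_session_scale(table, calibration)
    )
    wscores = window_scores(metrics, weights, calibration, config.status_thresholds)
    totals = np.array([w.total for w in wscores])
    vf = np.array([w.valid_fraction for w in wscores])
    ok = ~np.isnan(totals) & (vf > 0)
    if not ok.any():
        raise ValueError("no scorable window in session")
    session_mean = float(np.sum(totals[ok] * vf[ok]) / np.sum(vf[ok]))
    return StressReport(
        windows=wscores,
        session_mean=session_mean,
        session_status=status(session_mean, config.status_thresholds),
        weights=weights,
        config_hash=config.config_hash(),
        fps=table.fps,
        source=table.source,
    )


@dataclass
class AblationResult:
    """Deviation from the all-features baseline per removed-feature subset."""

    deviations: dict[tuple[str, ...], float]
    by_size: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.by_size:
            sizes: dict[int, list[float]] = {}
            for subset, dev in self.deviations.items():
                sizes.setdefault(len(subset), []).append(dev)
            self.by_size = {k: float(np.mean(v)) for k, v in sorted(sizes.items())}


def ablation_analysis(
    table: TrajectoryTable,
    weights: FeatureWeights | None = None,
    calibration: ScoreCalibration | None = None,
    config: AppConfig | None = None,
    max_removed: int = 4,
) -> AblationResult:
    """Weight-zero ablation: deviation of per-window totals from the
    five-feature baseline for every subset of removed features.

    Removing a subset is implemented by zeroing its weights, which by the
    weighted-mean algebra equals deleting those features.  Deviation is the
    mean absolute per-window difference versus the baseline totals.  The
    subset removing everything is skipped.
    """
    config = config or AppConfig(fps=table.fps)
    weights = weights or config.weights
    calibration = calibration or config.calibration
    metrics = windowed_metrics(
        table, config.window, scale=_session_scale(table, calibration)
    )
    per_window = [
        {f: feature_score(m, f, calibration) for f in FEATURES} for m in metrics
    ]

    def totals(w: FeatureWeights) -> np.ndarray:
        vals = []
        for s in per_window:
            try:
                vals.append(aggregate_score(s, w))
            except ValueError:
                vals.append(float("nan"))
        return np.array(vals)

    base = totals(weights)
    deviations: dict[tuple[str, ...], float] = {(): 0.0}
    for k in range(1, min(max_removed, len(FEATURES) - 1) + 1):
        for subset in itertools.combinations(FEATURES, k):
            if all(weights[f] == 0 for f in set(FEATURES) - set(subset)):
                continue  # would remove every effective feature
            sub = totals(weights.without(subset))
            deviations[tuple(f.value for f in subset)] = float(
                np.nanmean(np.abs(sub - base))
            )
    return AblationResult(deviations)
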