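"""Configuration objects: cleaning, window metrics, calibration, weights.

Everything tunable lives here, with defaults that make a textbook relaxed
simulated session score in the "okay" band (< 2 on the 0-10 scale) and a
textbook stressed one in the "stressed" band (> 8).  All thresholds are
expressed relative to a per-session body scale (the median inter-ear
distance) so that scores are invariant to camera distance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .landmarks import FEATURES, Feature

Knots = tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class CleaningConfig:
    """How low-confidence tracker output is repaired before analysis.

    likelihood_threshold: points with tracker confidence below this are
        treated as mistracked (the conventional tracker p-cutoff).
    max_gap_frames: runs of mistracked frames up to this length are filled
        by linear interpolation; longer runs are flagged missing.
    """

    likelihood_threshold: float = 0.6
    max_gap_frames: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.likelihood_threshold <= 1.0:
            raise ValueError("likelihood_threshold must be in [0, 1]")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")


@dataclass(frozen=True)
class WindowConfig:
    """Parameters of the per-window heuristics.

    window_s: evaluation window length in seconds (batch windows tumble,
        live windows trail).
    blink_max_s: eye closures shorter than this are blinks, not squints.
    closure_fraction: an eye counts as closed when its aperture falls below
        this fraction of the open-eye baseline aperture.
    freeze_activity_threshold: a window is freezing when the nose and both
        ear activity indices (scale-normalised, unitless) all fall below it.
    fold_range_threshold: an ear is immobile when its max range of motion is
        below this fraction of the body scale.
    fold_displacement_threshold: an immobile ear is folded when its window
        mean position is displaced from its session median by more than this
        fraction of the body scale.
    """

    window_s: float = 2.0
    blink_max_s: float = 1.0
    closure_fraction: float = 0.4
    freeze_activity_threshold: float = 0.12
    fold_range_threshold: float = 0.02
    fold_displacement_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.blink_max_s <= 0:
            raise ValueError("window_s and blink_max_s must be > 0")
        if not 0.0 < self.closure_fraction < 1.0:
            raise ValueError("closure_fraction must be in (0, 1)")


def _validate_knots(name: str, knots: Knots) -> None:
    xs = [k[0] for k in knots]
    if len(knots) < 2:
        raise ValueError(f"{name}: need at least 2 knots")
    if any(b <= a for a, b in zip(xs, xs[1:])):
        raise ValueError(f"{name}: knot x-values must be strictly increasing")
    if any(not 0.0 <= k[1] <= 10.0 for k in knots):
        raise ValueError(f"{name}: knot scores must lie in [0, 10]")


@dataclass(frozen=True)
class ScoreCalibration:
    """Piecewise-linear maps from window metrics to per-feature 0-10 scores.

    Each knot list maps a driving metric onto the score scale; evaluation is
    linear between knots and constant beyond the end knots.  Eye scores add
    a squint-coverage term and an aperture term; ear scores add fixed bumps
    for a detected fold and for left/right asymmetry.
    """

    #: fraction of window covered by squint-kind epochs -> score
    eye_squint_knots: Knots = ((0.0, 0.0), (0.6, 10.0))
    #: window-mean aperture relative to open-eye baseline -> score
    eye_aperture_knots: Knots = ((0.0, 4.0), (0.4, 0.0))
    #: nose activity index -> score (low activity = freezing = stressed)
    nose_activity_knots: Knots = ((0.0, 10.0), (0.12, 10.0), (0.4, 0.0))
    #: ear activity index -> score
    ear_activity_knots: Knots = ((0.0, 10.0), (0.1, 9.0), (0.13, 2.5), (0.22, 0.0))
    #: additive score bump when an ear fold is detected
    fold_bump: float = 4.0
    #: additive gain on the [0,1] ear asymmetry index
    asymmetry_gain: float = 3.0
    #: how the normalising body scale is obtained
    scale_definition: str = "inter_ear_median"  # or "config_constant"
    scale_constant: float = 200.0

    def __post_init__(self) -> None:
        for name in (
            "eye_squint_knots",
            "eye_aperture_knots",
            "nose_activity_knots",
            "ear_activity_knots",
        ):
            _validate_knots(name, getattr(self, name))
        if self.scale_definition not in ("inter_ear_median", "config_constant"):
            raise ValueError("scale_definition must be inter_ear_median or config_constant")
        if self.scale_constant <= 0:
            raise ValueError("scale_constant must be > 0")


@dataclass(frozen=True)
class FeatureWeights:
    """Per-feature non-negative weights; 0 excludes a feature entirely."""

    weights: Mapping[Feature, float] = field(
        default_factory=lambda: {f: 1.0 for f in FEATURES}
    )

    def __post_init__(self) -> None:
        w = {Feature(k): float(v) for k, v in self.weights.items()}
        for f in FEATURES:
            w.setdefault(f, 1.0)
        if any(v < 0 for v in w.values()):
            raise ValueError("weights must be non-negative")
        if all(v == 0 for v in w.values()):
            raise ValueError("at least one weight must be positive")
        object.__setattr__(self, "weights", w)

    def __getitem__(self, feature: Feature) -> float:
        return self.weights[Feature(feature)]

    def without(self, removed: Iterable[Feature]) -> "FeatureWeights":
        """Return a copy with the given features' weights set to zero."""
        removed = {Feature(f) for f in removed}
        return FeatureWeights(
            {f: (0.0 if f in removed else v) for f, v in self.weights.items()}
        )


@dataclass(frozen=True)
class LiveConfig:
    """Streaming-evaluation parameters.

    lookback_s: rolling history used for the live aperture baseline, body
        scale and ear median positions.
    hysteresis_frames: consecutive emissions required before the displayed
        status changes (anti-flicker).
    fallback_baseline_px: open-eye aperture used until any history exists.
    """

    lookback_s: float = 60.0
    hysteresis_frames: int = 15
    fallback_baseline_px: float = 20.0


@dataclass(frozen=True)
class AppConfig:
    """Top-level configuration bundle (YAML-loadable)."""

    fps: float = 30.0
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    calibration: ScoreCalibration = field(default_factory=ScoreCalibration)
    weights: FeatureWeights = field(default_factory=FeatureWeights)
    #: (t_caution, t_stressed) cut points on the 0-10 scale
    status_thresholds: tuple[float, float] = (10.0 / 3.0, 20.0 / 3.0)
    live: LiveConfig = field(default_factory=LiveConfig)
    #: external bodypart label -> canonical landmark name
    landmark_aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        t_c, t_s = self.status_thresholds
        if not 0.0 <= t_c < t_s <= 10.0:
            raise ValueError("status thresholds must satisfy 0 <= t_caution < t_stressed <= 10")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["weights"] = {f.value: v for f, v in self.weights.weights.items()}
        d["landmark_aliases"] = dict(self.landmark_aliases)
        return d

    def config_hash(self) -> str:
        """Stable short hash of the full configuration (report provenance)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _knots(v: Sequence[Sequence[float]]) -> Knots:
    return tuple((float(a), float(b)) for a, b in v)


def load_config(path: str | Path) -> AppConfig:
    """Load an :class:`AppConfig` from a YAML file.

    Only keys present in the file override defaults; unknown keys raise.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {
        "fps",
        "cleaning",
        "metrics",
        "calibration",
        "weights",
        "status_thresholds",
        "live",
        "landmark_aliases",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    kwargs: dict = {}
    if "fps" in raw:
        kwargs["fps"] = float(raw["fps"])
    if "cleaning" in raw:
        kwargs["cleaning"] = CleaningConfig(**raw["cleaning"])
    if "metrics" in raw:
        kwargs["window"] = WindowConfig(**raw["metrics"])
    if "calibration" in raw:
        cal = dict(raw["calibration"])
        for k in list(cal):
            if k.endswith("_knots"):
                cal[k] = _knots(cal[k])
        kwargs["calibration"] = ScoreCalibration(**cal)
    if "weights" in raw:
        kwargs["weights"] = FeatureWeights(
            {Feature(k): float(v) for k, v in raw["weights"].items()}
        )
    if "status_thresholds" in raw:
        t = raw["status_thresholds"]
        kwargs["status_thresholds"] = (float(t[0]), float(t[1]))
    if "live" in raw:
        kwargs["live"] = LiveConfig(**raw["live"])
    if "landmark_aliases" in raw:
        kwargs["landmark_aliases"] = dict(raw["landmark_aliases"])
    return AppConfig(**kwargs)


def dump_config(config: AppConfig, path: str | Path) -> Path:
    """Write a config back to YAML (keys mirror :func:`load_config`)."""
    d = config.to_dict()
    d["metrics"] = d.pop("window")
    d["calibration"] = {
        k: ([list(p) for p in v] if k.endswith("_knots") else v)
        for k, v in d["calibration"].items()
    }
    d["status_thresholds"] = list(d["status_thresholds"])
    path = Path(path)
    path.write_text(yaml.safe_dump(d, sort_keys=True))
    return path
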