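"""Synthetic 7-landmark facial sessions with ground-truth state labels.

The generator emulates what a markerless tracker emits for a head-fixed
mouse filmed from the front: slowly wandering nose and ear positions,
eyelid pairs whose aperture collapses during blinks (sub-second) and
squints (>= 1 s), freezing spans with near-zero motion, an ear pinned away
from its resting position (fold), isotropic Gaussian tracker jitter, and
Bernoulli low-likelihood dropouts.  Every run is fully reproducible from
its seed, and the event log gives frame-accurate ground truth for
detector recall/precision tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .keypoint_io import TrajectoryTable
from .landmarks import LANDMARK_INDEX, N_LANDMARKS, Landmark

RELAXED = "relaxed"
STRESSED_SQUINT = "stressed_squint"
STRESSED_FREEZE = "stressed_freeze"
STRESSED_EAR_FOLD = "stressed_ear_fold"
STRESSED_COMBINED = "stressed_combined"
STATES = (RELAXED, STRESSED_SQUINT, STRESSED_FREEZE, STRESSED_EAR_FOLD, STRESSED_COMBINED)

#: states whose spans squint / freeze / pin an ear
_SQUINT_STATES = {STRESSED_SQUINT, STRESSED_COMBINED}
_FREEZE_STATES = {STRESSED_FREEZE, STRESSED_COMBINED}
_FOLD_STATES = {STRESSED_EAR_FOLD, STRESSED_COMBINED}
#: blinks are generated only outside squint spans so truth stays clean
_BLINK_STATES = {RELAXED, STRESSED_FREEZE, STRESSED_EAR_FOLD}


@dataclass(frozen=True)
class Geometry:
    """Baseline landmark layout in pixels (1080p front-camera framing)."""

    nose: tuple[float, float] = (960.0, 700.0)
    ear_left: tuple[float, float] = (860.0, 420.0)
    ear_right: tuple[float, float] = (1060.0, 420.0)
    eye_left: tuple[float, float] = (910.0, 540.0)
    eye_right: tuple[float, float] = (1010.0, 540.0)
    open_aperture: float = 20.0
    nose_bound: float = 30.0  # reflecting random-walk half-width
    ear_bound: float = 10.0
    fold_offset: tuple[float, float] = (60.0, 0.0)  # pinned-ear displacement

    @property
    def inter_ear(self) -> float:
        return math.dist(self.ear_left, self.ear_right)


def _default_nose_sd() -> dict[str, float]:
    return {
        RELAXED: 2.0,
        STRESSED_SQUINT: 2.0,
        STRESSED_FREEZE: 0.0,
        STRESSED_EAR_FOLD: 2.0,
        STRESSED_COMBINED: 0.0,
    }


def _default_ear_sd() -> dict[str, float]:
    return {
        RELAXED: 0.8,
        STRESSED_SQUINT: 0.8,
        STRESSED_FREEZE: 0.0,
        STRESSED_EAR_FOLD: 0.8,
        STRESSED_COMBINED: 0.0,
    }


@dataclass
class SimulationConfig:
    """Study conditions of a simulated session.

    Durations in seconds, lengths in pixels.  Blink durations stay under
    one second and squint durations at or above it, so ground truth agrees
    with the blink/squint classification rule by construction.
    """

    fps: float = 30.0
    duration_s: float = 30.0
    geometry: Geometry = field(default_factory=Geometry)
    state_schedule: list[tuple[str, float]] | None = None
    blink_rate_per_min: float = 10.0
    blink_duration_s: tuple[float, float] = (0.2, 0.5)
    squint_duration_s: tuple[float, float] = (1.5, 5.0)
    squint_gap_s: tuple[float, float] = (2.0, 4.0)
    nose_step_sd: dict[str, float] = field(default_factory=_default_nose_sd)
    ear_step_sd: dict[str, float] = field(default_factory=_default_ear_sd)
    blink_aperture_fraction: float = 0.1
    squint_aperture_fraction: float = 0.2
    jitter_sd: float = 0.2
    dropout_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("duration_s and fps must be > 0")
        if self.blink_duration_s[1] >= 1.0:
            raise ValueError("blink durations must stay below 1 s")
        if self.squint_duration_s[0] < 1.0:
            raise ValueError("squint durations must be >= 1 s")
        if self.state_schedule is not None:
            for state, dur in self.state_schedule:
                if state not in STATES:
                    raise ValueError(f"unknown state {state!r}")
                if dur <= 0:
                    raise ValueError("schedule durations must be > 0")
            total = sum(d for _, d in self.state_schedule)
            if abs(total - self.duration_s) > 1.0 / self.fps:
                raise ValueError(
                    f"schedule totals {total} s but duration_s is {self.duration_s} s"
                )


@dataclass(frozen=True)
class SimEvent:
    kind: str  # "blink" | "squint" | "freeze" | "ear_fold"
    start_frame: int
    end_frame: int  # inclusive

    def duration_s(self, fps: float) -> float:
        return (self.end_frame - self.start_frame + 1) / fps


@dataclass
class SimulatedSession:
    """A trajectory table plus the ground truth that generated it."""

    table: TrajectoryTable
    truth: np.ndarray  # per-frame state label
    event_log: list[SimEvent]
    config: SimulationConfig

    def events(self, kind: str) -> list[SimEvent]:
        return [e for e in self.event_log if e.kind == kind]


def _frame_states(config: SimulationConfig, n: int) -> np.ndarray:
    if config.state_schedule is None:
        return np.full(n, RELAXED, dtype=object)
    states = np.empty(n, dtype=object)
    pos = 0
    for state, dur in config.state_schedule:
        k = round(dur * config.fps)
        states[pos : pos + k] = state
        pos += k
    states[pos:] = config.state_schedule[-1][0]
    return states[:n]


def _spans(states: np.ndarray, members: set[str]) -> list[tuple[int, int]]:
    """Maximal [start, stop) runs of frames whose state is in `members`."""
    mask = np.array([s in members for s in states])
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    return [(int(r[0]), int(r[-1]) + 1) for r in runs]


def _reflected_walk(
    rng: np.random.Generator, n: int, sd_per_frame: np.ndarray, bound: float
) -> np.ndarray:
    """1-D random walk with reflecting bounds at +/- bound, starting at 0."""
    steps = rng.normal(0.0, 1.0, n) * sd_per_frame
    out = np.empty(n)
    x = 0.0
    for i in range(n):
        x += steps[i]
        if x > bound:
            x = 2 * bound - x
        elif x < -bound:
            x = -2 * bound - x
        out[i] = x
    return out


def simulate_session(config: SimulationConfig) -> SimulatedSession:
    """Generate one session; bit-identical for identical config + seed."""
    rng = np.random.default_rng(config.seed)
    fps = config.fps
    n = round(config.duration_s * fps)
    geo = config.geometry
    states = _frame_states(config, n)
    events: list[SimEvent] = []

    nose_sd = np.array([config.nose_step_sd[s] for s in states])
    ear_sd = np.array([config.ear_step_sd[s] for s in states])

    xy = np.empty((n, N_LANDMARKS, 2))

    def walk2(base, sd, bound):
        return np.column_stack(
            [base[0] + _reflected_walk(rng, n, sd, bound),
             base[1] + _reflected_walk(rng, n, sd, bound)]
        )

    nose = walk2(geo.nose, nose_sd, geo.nose_bound)
    ear_r = walk2(geo.ear_right, ear_sd, geo.ear_bound)
    ear_l = walk2(geo.ear_left, ear_sd, geo.ear_bound)
    # ear fold: left ear pinned at a displaced position for the whole span
    for start, stop in _spans(states, _FOLD_STATES):
        ear_l[start:stop, 0] = geo.ear_left[0] + geo.fold_offset[0]
        ear_l[start:stop, 1] = geo.ear_left[1] + geo.fold_offset[1]
        events.append(SimEvent("ear_fold", start, stop - 1))
    for start, stop in _spans(states, _FREEZE_STATES):
        events.append(SimEvent("freeze", start, stop - 1))

    # eyelid aperture trace: open, with blink and squint closures
    aperture = np.full(n, geo.open_aperture)
    for start, stop in _spans(states, _BLINK_STATES):
        t = start / fps
        while True:
            t += rng.exponential(60.0 / config.blink_rate_per_min)
            d = rng.uniform(*config.blink_duration_s)
            if t + d >= stop / fps:
                break
            s_f = int(round(t * fps))
            n_f = max(1, int(round(d * fps)))
            aperture[s_f : s_f + n_f] = config.blink_aperture_fraction * geo.open_aperture
            events.append(SimEvent("blink", s_f, s_f + n_f - 1))
            t += d
    for start, stop in _spans(states, _SQUINT_STATES):
        t = start / fps + rng.uniform(*config.squint_gap_s) / 2
        while True:
            d = rng.uniform(*config.squint_duration_s)
            d = min(d, stop / fps - t)
            if d < 1.0:
                break
            s_f = int(np.floor(t * fps))
            n_f = int(np.ceil(d * fps))
            e_f = min(s_f + n_f, stop)
            aperture[s_f:e_f] = config.squint_aperture_fraction * geo.open_aperture
            events.append(SimEvent("squint", s_f, e_f - 1))
            t += d + rng.uniform(*config.squint_gap_s)
            if t >= stop / fps - 1.0:
                break

    half = aperture / 2.0
    for side, center in (("left", geo.eye_left), ("right", geo.eye_right)):
        upper, lower = (
            Landmark[f"EYELID_UPPER_{side.upper()}"],
            Landmark[f"EYELID_LOWER_{side.upper()}"],
        )
        xy[:, LANDMARK_INDEX[upper.value], 0] = center[0]
        xy[:, LANDMARK_INDEX[upper.value], 1] = center[1] - half
        xy[:, LANDMARK_INDEX[lower.value], 0] = center[0]
        xy[:, LANDMARK_INDEX[lower.value], 1] = center[1] + half

    xy[:, LANDMARK_INDEX[Landmark.NOSE.value], :] = nose
    xy[:, LANDMARK_INDEX[Landmark.EAR_LEFT.value], :] = ear_l
    xy[:, LANDMARK_INDEX[Landmark.EAR_RIGHT.value], :] = ear_r

    # tracker noise + dropouts
    xy += rng.normal(0.0, config.jitter_sd, xy.shape)
    likelihood = rng.uniform(0.85, 1.0, (n, N_LANDMARKS))
    drop = rng.random((n, N_LANDMARKS)) < config.dropout_rate
    likelihood[drop] = rng.uniform(0.05, 0.45, int(drop.sum()))
    xy[drop] += rng.normal(0.0, 20.0, (int(drop.sum()), 2))  # mistracked points

    table = TrajectoryTable(xy, likelihood, fps=fps, source=f"simulated(seed={config.seed})")
    for e in events:
        d = e.duration_s(fps)
        if e.kind == "blink":
            assert d < 1.0
        elif e.kind == "squint":
            assert d >= 1.0
    return SimulatedSession(table, states, sorted(events, key=lambda e: e.start_frame), config)


def make_validation_cohort(
    n_mice: int,
    stress_levels: Sequence[float],
    seed: int = 0,
    duration_s: float = 30.0,
    fps: float = 30.0,
) -> tuple[list[SimulatedSession], np.ndarray]:
    """One session per mouse; the stressed-state share of each session is
    its assigned true stress level in [0, 1].

    Returns the sessions and the true profile for correlation tests.
    """
    if n_mice != len(stress_levels):
        raise ValueError("n_mice must equal len(stress_levels)")
    levels = np.asarray(stress_levels, dtype=float)
    if np.any((levels < 0) | (levels > 1)):
        raise ValueError("stress levels must lie in [0, 1]")
    children = np.random.SeedSequence(seed).spawn(n_mice)
    sessions = []
    for level, child in zip(levels, children):
        schedule: list[tuple[str, float]] = []
        if level < 1.0:
            schedule.append((RELAXED, (1.0 - level) * duration_s))
        if level > 0.0:
            schedule.append((STRESSED_COMBINED, level * duration_s))
        cfg = SimulationConfig(
            fps=fps,
            duration_s=duration_s,
            state_schedule=schedule,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        sessions.append(simulate_session(cfg))
    return sessions, levels
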