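"""Streaming stress evaluation with a trailing window.

Frames arrive one at a time (e.g. piped from a live tracker over a TCP
socket as newline-delimited JSON); the monitor keeps exactly one trailing
window of frames plus a bounded rolling history of scalar context (eyelid
apertures, inter-ear distance, ear positions) for the live baseline, and
emits a score + status per ingested frame.  Emission is a pure function of
the buffer contents and the configuration, so replaying a frame log
reproduces the emission log exactly, and the final emission on a frozen
stream equals the trailing-window batch score on the same frames.

Low-confidence points are treated as missing in live mode (no
interpolation): the gap-filling used in batch cleaning needs future
frames, which a live stream does not have.
"""

from __future__ import annotations

import json
import socketserver
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .config import AppConfig
from .facial_metrics import (
    compute_aperture_baseline,
    euclidean_distance,
    windowed_metrics,
)
from .keypoint_io import TrajectoryTable
from .landmarks import EARS, EYELID_PAIRS, LANDMARK_INDEX, LANDMARKS, N_LANDMARKS, Landmark
from .stress_scoring import window_scores

WARMING_UP = "warming_up"


@dataclass(frozen=True)
class FrameMessage:
    """One frame of landmark records from the tracker."""

    frame_idx: int
    timestamp: float
    landmarks: dict[str, tuple[float, float, float]]  # name -> (x, y, likelihood)

    @classmethod
    def from_json(cls, line: str) -> "FrameMessage":
        d = json.loads(line)
        return cls(
            frame_idx=int(d["frame_idx"]),
            timestamp=float(d.get("timestamp", 0.0)),
            landmarks={k: tuple(map(float, v)) for k, v in d["landmarks"].items()},
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "frame_idx": self.frame_idx,
                "timestamp": self.timestamp,
                "landmarks": {k: list(v) for k, v in self.landmarks.items()},
            }
        )


@dataclass(frozen=True)
class StatusMessage:
    """One emission: score on 0-10 (None while warming up) and status."""

    frame_idx: int
    score: float | None
    status: str

    def to_json(self) -> str:
        return json.dumps(
            {"frame_idx": self.frame_idx, "score": self.score, "status": self.status}
        )


def _frame_arrays(
    msg: FrameMessage | None, likelihood_threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """(7, 2) coordinates and (7,) likelihoods; sub-threshold -> missing."""
    xy = np.full((N_LANDMARKS, 2), np.nan)
    lik = np.zeros(N_LANDMARKS)
    if msg is not None:
        for name, (x, y, p) in msg.landmarks.items():
            j = LANDMARK_INDEX.get(name)
            if j is None:
                continue
            lik[j] = p
            if p >= likelihood_threshold and np.isfinite(x) and np.isfinite(y):
                xy[j] = (x, y)
    return xy, lik


class LiveMonitor:
    """Rolling-buffer evaluator mirroring the batch pipeline.

    Memory is bounded: one window of frames plus ``lookback_s`` seconds of
    scalar context, regardless of stream length.
    """

    def __init__(self, config: AppConfig | None = None):
        self.config = config or AppConfig()
        fps = self.config.fps
        self.window_n = round(self.config.window.window_s * fps)
        lookback_n = round(self.config.live.lookback_s * fps)
        self._buffer: deque[tuple[np.ndarray, np.ndarray]] = deque(maxlen=self.window_n)
        self._aperture: dict[str, deque[float]] = {
            side: deque(maxlen=lookback_n) for side in ("left", "right")
        }
        self._inter_ear: deque[float] = deque(maxlen=lookback_n)
        self._ear_pos: dict[str, deque[tuple[float, float]]] = {
            side: deque(maxlen=lookback_n) for side in ("left", "right")
        }
        self._last_idx: int | None = None
        self._displayed: str = WARMING_UP
        self._candidate: str | None = None
        self._candidate_run = 0
        self.dropped: int = 0  # out-of-order frames seen

    # -- ingestion ---------------------------------------------------------

    def ingest_frame(self, msg: FrameMessage) -> None:
        """Add one frame; gaps in frame_idx register as missing frames and
        out-of-order frames are dropped (counted in ``self.dropped``)."""
        if self._last_idx is not None and msg.frame_idx <= self._last_idx:
            self.dropped += 1
            return
        if self._last_idx is not None:
            for _ in range(msg.frame_idx - self._last_idx - 1):
                self._push(None)
        self._push(msg)
        self._last_idx = msg.frame_idx

    def _push(self, msg: FrameMessage | None) -> None:
        xy, lik = _frame_arrays(msg, self.config.cleaning.likelihood_threshold)
        self._buffer.append((xy, lik))
        for side in ("left", "right"):
            upper, lower = EYELID_PAIRS[side]
            d = euclidean_distance(
                xy[LANDMARK_INDEX[upper.value]], xy[LANDMARK_INDEX[lower.value]]
            )
            self._aperture[side].append(float(d))
            ex, ey = xy[LANDMARK_INDEX[EARS[side].value]]
            self._ear_pos[side].append((float(ex), float(ey)))
        self._inter_ear.append(
            float(
                euclidean_distance(
                    xy[LANDMARK_INDEX[Landmark.EAR_LEFT.value]],
                    xy[LANDMARK_INDEX[Landmark.EAR_RIGHT.value]],
                )
            )
        )

    # -- context -----------------------------------------------------------

    def _context(self):
        """Rolling equivalents of the session-level batch context."""
        baselines = {}
        for side in ("left", "right"):
            hist = np.array(self._aperture[side])
            try:
                baselines[side] = compute_aperture_baseline(hist)
            except ValueError:
                baselines[side] = self.config.live.fallback_baseline_px
        ie = np.array(self._inter_ear)
        scale = (
            float(np.nanmedian(ie))
            if not np.all(np.isnan(ie))
            else self.config.calibration.scale_constant
        )
        ear_medians = {}
        for side in ("left", "right"):
            pos = np.array(self._ear_pos[side])
            ear_medians[side] = (
                np.nanmedian(pos, axis=0)
                if not np.all(np.isnan(pos))
                else np.array([np.nan, np.nan])
            )
        return scale, baselines, ear_medians

    # -- emission ----------------------------------------------------------

    def emit_status(self) -> StatusMessage:
        """Score the trailing window; WARMING_UP until the buffer fills."""
        idx = self._last_idx if self._last_idx is not None else -1
        if len(self._buffer) < self.window_n:
            return StatusMessage(idx, None, WARMING_UP)
        xy = np.stack([f[0] for f in self._buffer])
        lik = np.stack([f[1] for f in self._buffer])
        table = TrajectoryTable(xy, lik, fps=self.config.fps, source="live-buffer")
        scale, baselines, ear_medians = self._context()
        metrics = windowed_metrics(
            table,
            self.config.window,
            scale=scale,
            baselines=baselines,
            ear_medians=ear_medians,
        )
        ws = window_scores(
            metrics, self.config.weights, self.config.calibration,
            self.config.status_thresholds,
        )[0]
        raw_status = ws.status if not np.isnan(ws.total) else WARMING_UP
        score = None if np.isnan(ws.total) else float(ws.total)
        return StatusMessage(idx, score, self._hysteresis(raw_status))

    def _hysteresis(self, raw: str) -> str:
        """Require k consecutive identical raw statuses before switching."""
        if self._displayed == WARMING_UP:
            self._displayed = raw
            return raw
        if raw == self._displayed:
            self._candidate, self._candidate_run = None, 0
            return self._displayed
        if raw == self._candidate:
            self._candidate_run += 1
        else:
            self._candidate, self._candidate_run = raw, 1
        if self._candidate_run >= self.config.live.hysteresis_frames:
            self._displayed = raw
            self._candidate, self._candidate_run = None, 0
        return self._displayed


def frames_from_table(table: TrajectoryTable) -> Iterator[FrameMessage]:
    """Turn a trajectory table into a stream of frame messages."""
    for i in range(table.n_frames):
        landmarks = {}
        for lm in LANDMARKS:
            j = LANDMARK_INDEX[lm.value]
            x, y = table.xy[i, j]
            p = table.likelihood[i, j]
            if np.isnan(x) or np.isnan(y):
                x, y, p = 0.0, 0.0, 0.0  # missing encoded as likelihood 0
            landmarks[lm.value] = (float(x), float(y), float(p))
        yield FrameMessage(i, i / table.fps, landmarks)


def replay(
    messages: Iterable[FrameMessage], config: AppConfig | None = None
) -> list[StatusMessage]:
    """Feed a message log through a fresh monitor; one emission per frame."""
    monitor = LiveMonitor(config)
    out = []
    for msg in messages:
        monitor.ingest_frame(msg)
        out.append(monitor.emit_status())
    return out


def score_trailing_window(
    table: TrajectoryTable, config: AppConfig | None = None, end_frame: int | None = None
):
    """Batch counterpart of one live emission.

    Scores the window of frames ending at ``end_frame`` (exclusive;
    default: end of table) using rolling context computed from the
    preceding ``lookback_s`` seconds — the consistency contract for
    batch/live equivalence.  Low-confidence points are masked to missing,
    exactly as in live ingestion.  Returns a :class:`WindowScore`.
    """
    config = config or AppConfig(fps=table.fps)
    end = table.n_frames if end_frame is None else end_frame
    window_n = round(config.window.window_s * table.fps)
    if end < window_n:
        raise ValueError("not enough frames before end_frame for one window")
    lookback_n = round(config.live.lookback_s * table.fps)
    hist = table.slice(max(0, end - lookback_n), end)

    # mask sub-threshold points to missing (live-mode cleaning)
    xy = hist.xy.copy()
    xy[hist.likelihood < config.cleaning.likelihood_threshold] = np.nan
    hist = TrajectoryTable(xy, hist.likelihood, fps=table.fps, source=table.source)

    baselines = {}
    for side in ("left", "right"):
        upper, lower = EYELID_PAIRS[side]
        ap = euclidean_distance(hist.landmark_xy(upper), hist.landmark_xy(lower))
        try:
            baselines[side] = compute_aperture_baseline(ap)
        except ValueError:
            baselines[side] = config.live.fallback_baseline_px
    ie = euclidean_distance(
        hist.landmark_xy(Landmark.EAR_LEFT), hist.landmark_xy(Landmark.EAR_RIGHT)
    )
    scale = (
        float(np.nanmedian(ie))
        if not np.all(np.isnan(ie))
        else config.calibration.scale_constant
    )
    ear_medians = {}
    for side, lm in EARS.items():
        pos = hist.landmark_xy(lm)
        ear_medians[side] = (
            np.nanmedian(pos, axis=0)
            if not np.all(np.isnan(pos))
            else np.array([np.nan, np.nan])
        )
    window = hist.slice(hist.n_frames - window_n, hist.n_frames)
    metrics = windowed_metrics(
        window, config.window, scale=scale, baselines=baselines, ear_medians=ear_medians
    )
    return window_scores(
        metrics, config.weights, config.calibration, config.status_thresholds
    )[0]


class _LineHandler(socketserver.StreamRequestHandler):
    def handle(self) -> None:  # pragma: no cover - thin network shim
        monitor: LiveMonitor = self.server.monitor  # type: ignore[attr-defined]
        for raw in self.rfile:
            line = raw.decode().strip()
            if not line:
                continue
            monitor.ingest_frame(FrameMessage.from_json(line))
            self.wfile.write((monitor.emit_status().to_json() + "\n").encode())


def serve(port: int, config: AppConfig | None = None) -> None:  # pragma: no cover
    """Serve newline-delimited JSON frames over TCP; one status per frame."""
    server = socketserver.TCPServer(("0.0.0.0", port), _LineHandler)
    server.monitor = LiveMonitor(config)  # type: ignore[attr-defined]
    server.serve_forever()
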