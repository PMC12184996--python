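"""Read, validate, clean and write facial-landmark trajectory tables.

The on-disk formats are the de-facto markerless-tracking exports: a CSV
with three header rows (scorer / bodyparts / coords) and one leading
frame-index column, with an ``x, y, likelihood`` triplet per landmark, or
the equivalent single-table HDF5 layout.  Neither format carries a frame
rate, so ``fps`` is supplied out of band (config or CLI flag).

Coordinates follow the image convention: origin top-left, x rightward,
y downward, units pixels.  Missing points are encoded as NaN coordinates.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import CleaningConfig
from .landmarks import LANDMARK_INDEX, LANDMARKS, N_LANDMARKS, Landmark


class SchemaError(ValueError):
    """The file's landmark columns do not match the 7-landmark schema."""


class ParseError(ValueError):
    """The file's header structure is malformed."""


class TrajectoryTable:
    """Per-frame (x, y, likelihood) for the seven facial landmarks.

    Attributes
    ----------
    xy : (n_frames, 7, 2) float array; NaN marks a missing point.
    likelihood : (n_frames, 7) float array in [0, 1].
    fps : frames per second (> 0); not stored in the file formats.
    source : free-text provenance.
    """

    def __init__(self, xy, likelihood, fps: float = 30.0, source: str = ""):
        self.xy = np.asarray(xy, dtype=float)
        self.likelihood = np.asarray(likelihood, dtype=float)
        self.fps = float(fps)
        self.source = source
        self.validate()

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    def validate(self) -> None:
        if self.xy.ndim != 3 or self.xy.shape[1:] != (N_LANDMARKS, 2):
            raise SchemaError(f"xy must have shape (n, {N_LANDMARKS}, 2), got {self.xy.shape}")
        if self.likelihood.shape != self.xy.shape[:2]:
            raise SchemaError("likelihood shape must match xy frames x landmarks")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        with np.errstate(invalid="ignore"):
            bad = (self.likelihood < 0) | (self.likelihood > 1)
        if np.any(bad & ~np.isnan(self.likelihood)):
            raise ValueError("likelihoods must lie in [0, 1]")
        if np.any(np.isinf(self.xy)):
            raise ValueError("coordinates must be finite or NaN (missing)")

    def landmark_xy(self, landmark: Landmark | str) -> np.ndarray:
        """(n_frames, 2) positions of one landmark."""
        return self.xy[:, LANDMARK_INDEX[Landmark(landmark).value], :]

    def landmark_likelihood(self, landmark: Landmark | str) -> np.ndarray:
        return self.likelihood[:, LANDMARK_INDEX[Landmark(landmark).value]]

    def slice(self, start: int, stop: int) -> "TrajectoryTable":
        """Sub-table over the frame range [start, stop)."""
        return TrajectoryTable(
            self.xy[start:stop], self.likelihood[start:stop], self.fps, self.source
        )

    def copy(self) -> "TrajectoryTable":
        return TrajectoryTable(self.xy.copy(), self.likelihood.copy(), self.fps, self.source)

    def equals(self, other: "TrajectoryTable") -> bool:
        return (
            self.xy.shape == other.xy.shape
            and np.array_equal(self.xy, other.xy, equal_nan=True)
            and np.array_equal(self.likelihood, other.likelihood, equal_nan=True)
        )

    def to_dataframe(self, scorer: str = "stressface") -> pd.DataFrame:
        """Tracking-dialect DataFrame: MultiIndex (scorer, bodyparts, coords)."""
        cols = pd.MultiIndex.from_tuples(
            [
                (scorer, lm.value, coord)
                for lm in LANDMARKS
                for coord in ("x", "y", "likelihood")
            ],
            names=["scorer", "bodyparts", "coords"],
        )
        n = self.n_frames
        data = np.empty((n, N_LANDMARKS * 3))
        data[:, 0::3] = self.xy[:, :, 0]
        data[:, 1::3] = self.xy[:, :, 1]
        data[:, 2::3] = self.likelihood
        return pd.DataFrame(data, index=pd.RangeIndex(n), columns=cols)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        fps: float = 30.0,
        source: str = "",
        aliases: Mapping[str, str] | None = None,
    ) -> "TrajectoryTable":
        """Build a table from a tracking-dialect DataFrame, applying aliases."""
        if df.columns.nlevels != 3:
            raise ParseError(
                f"expected 3 header levels (scorer/bodyparts/coords), got {df.columns.nlevels}"
            )
        aliases = dict(aliases or {})
        bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
        canonical = {bp: aliases.get(bp, bp) for bp in bodyparts}
        have = set(canonical.values())
        want = {lm.value for lm in LANDMARKS}
        missing, extra = sorted(want - have), sorted(have - want)
        if missing or extra:
            raise SchemaError(
                f"landmark columns do not match schema; missing={missing}, extra={extra}"
            )
        n = len(df)
        xy = np.full((n, N_LANDMARKS, 2), np.nan)
        lik = np.full((n, N_LANDMARKS), np.nan)
        scorer = df.columns.get_level_values(0)[0]
        for bp, name in canonical.items():
            j = LANDMARK_INDEX[name]
            sub = df[scorer][bp]
            for coord in ("x", "y", "likelihood"):
                if coord not in sub.columns:
                    raise SchemaError(f"landmark {bp!r} lacks a {coord!r} column")
            xy[:, j, 0] = pd.to_numeric(sub["x"], errors="coerce").to_numpy(float)
            xy[:, j, 1] = pd.to_numeric(sub["y"], errors="coerce").to_numpy(float)
            lik[:, j] = pd.to_numeric(sub["likelihood"], errors="coerce").to_numpy(float)
        lik = np.where(np.isnan(lik), 0.0, lik)
        return cls(xy, lik, fps=fps, source=source)


def _check_csv_header(path: Path) -> None:
    with open(path) as fh:
        for lineno, expected in ((1, "scorer"), (2, "bodyparts"), (3, "coords")):
            line = fh.readline()
            if not line:
                raise ParseError(f"{path}: line {lineno}: expected {expected!r} header row")
            first = line.split(",", 1)[0].strip()
            if first != expected:
                raise ParseError(
                    f"{path}: line {lineno}: expected header row starting with "
                    f"{expected!r}, found {first!r}"
                )


def read_trajectories(
    path: str | Path,
    dialect: str = "csv3header",
    fps: float = 30.0,
    aliases: Mapping[str, str] | None = None,
) -> TrajectoryTable:
    """Read a trajectory table from disk.

    Parameters
    ----------
    dialect : "csv3header" (3 header rows) or "h5".
    fps : frame rate; the formats store none.
    aliases : external bodypart label -> canonical landmark name.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv3header":
        _check_csv_header(path)
        df = pd.read_csv(
            path, header=[0, 1, 2], index_col=0, float_precision="round_trip"
        )
    elif dialect == "h5":
        df = pd.read_hdf(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return TrajectoryTable.from_dataframe(df, fps=fps, source=str(path), aliases=aliases)


def write_trajectories(
    table: TrajectoryTable,
    path: str | Path,
    dialect: str = "csv3header",
    scorer: str = "stressface",
) -> Path:
    """Write a table to disk; the file reads back to an equal table.

    CSV numbers are written at full float precision (repr), so the
    roundtrip is value-exact.
    """
    path = Path(path)
    df = table.to_dataframe(scorer=scorer)
    if dialect == "csv3header":
        df.to_csv(path)
    elif dialect == "h5":
        df.to_hdf(path, key="trajectories", mode="w")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def clean_trajectories(table: TrajectoryTable, config: CleaningConfig) -> TrajectoryTable:
    """Repair low-confidence points.

    Points with ``likelihood < likelihood_threshold`` are replaced by
    linear interpolation (per coordinate, independently in x and y) from
    the nearest confident neighbours when the low-confidence run is at
    most ``max_gap_frames`` long and bounded on both sides; otherwise the
    points are flagged missing (NaN).  Confident points are never altered,
    so cleaning is idempotent.
    """
    xy = table.xy.copy()
    n = table.n_frames
    for j, lm in enumerate(LANDMARKS):
        conf = table.likelihood[:, j] >= config.likelihood_threshold
        # NaN coordinates are untrustworthy regardless of likelihood
        conf = conf & ~np.isnan(table.xy[:, j, :]).any(axis=1)
        if n and not conf.any():
            raise ValueError(f"landmark {lm.value!r} has no confident frames")
        if conf.all():
            continue
        idx_conf = np.flatnonzero(conf)
        bad = np.flatnonzero(~conf)
        # split the bad frames into maximal runs
        runs = np.split(bad, np.flatnonzero(np.diff(bad) > 1) + 1)
        for run in runs:
            lo, hi = run[0], run[-1]
            interior = lo > idx_conf[0] and hi < idx_conf[-1]
            if interior and len(run) <= config.max_gap_frames:
                for c in (0, 1):
                    xy[run, j, c] = np.interp(run, idx_conf, table.xy[idx_conf, j, c])
            else:
                xy[run, j, :] = np.nan
    return TrajectoryTable(xy, table.likelihood.copy(), table.fps, table.source)
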