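"""Telemetry preprocessing: quality filters, classification, synchronization.

Detection tables are pandas DataFrames with columns ``fish_id``, ``t``
(seconds from trial start), ``x`` and ``y`` (meters).  Preprocessing

* drops whole trajectories whose position variability (standard deviation of
  consecutive position-increment magnitudes) falls below 20% of the fish's
  overall variability in any 1-h sliding window — the signature of an
  expelled transmitter resting on the pond bottom;
* splits trajectories at detection gaps longer than 1 h (poor detection);
* classifies every position as ``shade_day``, ``open_day`` or ``night``
  (night positions are not split by location);
* resamples all fish onto a common 4-s grid by nearest-neighbor
  interpolation so that frame-level school quantities can be computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import PondGeometry, TrialSchedule

__all__ = [
    "DETECTION_COLUMNS",
    "ExpelledFilterResult",
    "FrameSet",
    "read_detections",
    "write_detections",
    "filter_expelled_transmitters",
    "drop_expelled",
    "filter_detection_gaps",
    "classify_position",
    "classify_detections",
    "synchronize_tracks",
]

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = ("fish_id", "t", "x", "y")

CATEGORIES = ("shade_day", "open_day", "night")


def read_detections(path) -> pd.DataFrame:
    """Read a detection CSV (fish_id, t, x, y), sorted by fish and time."""
    df = pd.read_csv(path)
    missing = set(DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detection table missing columns {sorted(missing)}")
    return df.sort_values(["fish_id", "t"], kind="stable").reset_index(drop=True)


def write_detections(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _increments(traj: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Magnitudes of consecutive position increments and their end times."""
    x = traj["x"].to_numpy(float)
    y = traj["y"].to_numpy(float)
    t = traj["t"].to_numpy(float)
    if np.any(np.diff(t) < 0):
        raise ValueError("timestamps must be non-decreasing within a fish")
    d = np.hypot(np.diff(x), np.diff(y))
    return d, t[1:]


@dataclass(frozen=True)
class ExpelledFilterResult:
    """Verdict of the expelled-transmitter filter on one trajectory."""

    drop: bool
    flagged_windows: tuple
    overall_sd: float
    n_windows: int


def filter_expelled_transmitters(
    trajectory: pd.DataFrame,
    window: float = 3600.0,
    ratio: float = 0.2,
    hop: float = 60.0,
) -> ExpelledFilterResult:
    """Flag low-variability windows betraying an expelled transmitter.

    The standard deviation of consecutive position-increment magnitudes is
    computed in sliding windows of length ``window`` (advanced by ``hop``);
    windows with sd below ``ratio`` times the overall sd are flagged and any
    flagged trajectory is dropped in its entirety.

    The relative rule is blind to a tag that was already stationary at the
    first detection (its variability is then uniformly low), so a
    deterministic stationarity rule replaces the original visual check: a
    trajectory whose total spatial extent is no more than ten times its
    median increment magnitude never swam anywhere and is dropped.
    """
    if len(trajectory) < 2:
        raise ValueError("trajectory needs at least 2 detections")
    if window <= 0 or not 0.0 < ratio < 1.0:
        raise ValueError("window must be > 0 and ratio in (0, 1)")
    d, td = _increments(trajectory)
    overall_sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0

    x = trajectory["x"].to_numpy(float)
    y = trajectory["y"].to_numpy(float)
    extent = float(np.hypot(x.max() - x.min(), y.max() - y.min()))
    if extent <= 10.0 * float(np.median(d)):
        return ExpelledFilterResult(True, (), overall_sd, 0)

    if overall_sd <= 1e-9 * float(np.mean(d)):
        # numerically constant increments (exactly uniform motion) carry no
        # expelled-tag signature
        return ExpelledFilterResult(False, (), overall_sd, 0)

    t0, t1 = td[0], td[-1]
    starts = np.arange(t0, max(t1 - window, t0) + hop / 2, hop)
    # prefix sums for O(1) per-window mean/sd
    c1 = np.concatenate([[0.0], np.cumsum(d)])
    c2 = np.concatenate([[0.0], np.cumsum(d**2)])
    lo = np.searchsorted(td, starts, side="left")
    hi = np.searchsorted(td, starts + window, side="right")
    n = (hi - lo).astype(float)
    flagged = []
    with np.errstate(invalid="ignore"):
        s1 = c1[hi] - c1[lo]
        s2 = c2[hi] - c2[lo]
        var = (s2 - s1**2 / n) / (n - 1)
    for i, start in enumerate(starts):
        if n[i] < 2:
            continue
        sd = np.sqrt(max(var[i], 0.0))
        if sd < ratio * overall_sd:
            flagged.append((float(start), float(start + window)))
    usable = int(np.sum(n >= 2))
    return ExpelledFilterResult(bool(flagged), tuple(flagged), overall_sd, usable)


def drop_expelled(
    detections: pd.DataFrame,
    window: float = 3600.0,
    ratio: float = 0.2,
    hop: float = 60.0,
) -> tuple[pd.DataFrame, dict]:
    """Apply the expelled-transmitter filter per fish; drop flagged fish."""
    verdicts = {}
    keep = []
    for fish_id, traj in detections.groupby("fish_id", sort=True):
        res = filter_expelled_transmitters(traj, window=window, ratio=ratio, hop=hop)
        verdicts[fish_id] = res
        if not res.drop:
            keep.append(traj)
        else:
            logger.info(
                "dropping fish %s: %d flagged low-variability windows",
                fish_id,
                len(res.flagged_windows),
            )
    kept = (
        pd.concat(keep, ignore_index=True)
        if keep
        else detections.iloc[0:0].copy()
    )
    return kept, verdicts


def filter_detection_gaps(
    trajectory: pd.DataFrame, max_gap: float = 3600.0
) -> list[pd.DataFrame]:
    """Split a trajectory at inter-detection gaps strictly longer than max_gap.

    The gap itself is excised (no interpolation across it); both flanking
    segments are kept.  A gap of exactly ``max_gap`` is retained.
    """
    t = trajectory["t"].to_numpy(float)
    if np.any(np.diff(t) < 0):
        raise ValueError("timestamps must be sorted")
    breaks = np.flatnonzero(np.diff(t) > max_gap) + 1
    pieces = np.split(np.arange(len(trajectory)), breaks)
    return [trajectory.iloc[idx].reset_index(drop=True) for idx in pieces]


def classify_position(
    x,
    y,
    t,
    geometry: PondGeometry,
    schedule: TrialSchedule,
    shade_label: str | None = None,
):
    """Category of one or more positions: shade_day / open_day / night.

    Night is decided purely by the clock; daytime positions are shade_day
    iff they fall inside (or on the boundary of) the active shade square.
    Raises if a position lies outside the pond.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    inside = geometry.inside_pond(x, y)
    if not np.all(inside):
        bad = np.flatnonzero(~inside)[0]
        raise ValueError(f"position ({x[bad]}, {y[bad]}) lies outside the pond")
    day = np.atleast_1d(schedule.is_day(t))
    shade = geometry.under_shade(x, y, shade_label)
    out = np.where(day, np.where(shade, "shade_day", "open_day"), "night")
    return out if out.size > 1 else str(out[0])


def classify_detections(
    detections: pd.DataFrame,
    geometry: PondGeometry,
    schedule: TrialSchedule,
    shade_label: str | None = None,
) -> pd.DataFrame:
    """Return a copy with ``under_shade``, ``is_day`` and ``category`` columns."""
    out = detections.copy()
    x = out["x"].to_numpy(float)
    y = out["y"].to_numpy(float)
    t = out["t"].to_numpy(float)
    out["under_shade"] = geometry.under_shade(x, y, shade_label)
    out["is_day"] = schedule.is_day(t)
    out["category"] = np.where(
        out["is_day"],
        np.where(out["under_shade"], "shade_day", "open_day"),
        "night",
    )
    return out


@dataclass(frozen=True)
class FrameSet:
    """Per-fish positions synchronized on a common regular time grid.

    ``xy`` has shape (n_times, n_fish, 2); ``valid`` marks grid points where
    a fish had a detection within half a grid step.
    """

    times: np.ndarray
    fish_ids: tuple
    xy: np.ndarray
    valid: np.ndarray
    dt: float

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def n_fish(self) -> int:
        return len(self.fish_ids)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (time, fish_id, x, y, valid)."""
        t = np.repeat(self.times, self.n_fish)
        fid = np.tile(np.asarray(self.fish_ids, dtype=object), self.n_frames)
        xy = self.xy.reshape(-1, 2)
        return pd.DataFrame(
            {
                "time": t,
                "fish_id": fid,
                "x": xy[:, 0],
                "y": xy[:, 1],
                "valid": self.valid.reshape(-1),
            }
        )

    def to_detections(self) -> pd.DataFrame:
        """Valid grid positions as a plain detection table."""
        df = self.to_frame()
        df = df[df["valid"]].rename(columns={"time": "t"})
        return df[["fish_id", "t", "x", "y"]].reset_index(drop=True)


def synchronize_tracks(
    detections: pd.DataFrame,
    dt: float = 4.0,
    t0: float | None = None,
    t1: float | None = None,
) -> FrameSet:
    """Nearest-neighbor resampling of all fish onto a common ``dt`` grid.

    Each grid time takes the detection nearest in time for each fish
    (earlier detection wins exact ties).  Grid points with no detection
    within ``dt / 2`` are marked invalid rather than carrying a stale fix.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if len(detections) == 0:
        raise ValueError("no detections to synchronize")
    tmin = float(detections["t"].min()) if t0 is None else float(t0)
    tmax = float(detections["t"].max()) if t1 is None else float(t1)
    start = np.floor(tmin / dt) * dt
    n_frames = int(np.floor((tmax - start) / dt)) + 1
    times = start + dt * np.arange(n_frames)

    fish_ids = tuple(sorted(detections["fish_id"].unique()))
    xy = np.full((n_frames, len(fish_ids), 2), np.nan)
    valid = np.zeros((n_frames, len(fish_ids)), dtype=bool)
    half = dt / 2.0

    for j, fid in enumerate(fish_ids):
        traj = detections[detections["fish_id"] == fid].sort_values("t", kind="stable")
        tt = traj["t"].to_numpy(float)
        pos = traj[["x", "y"]].to_numpy(float)
        right = np.searchsorted(tt, times, side="left")
        left = np.clip(right - 1, 0, len(tt) - 1)
        right = np.clip(right, 0, len(tt) - 1)
        d_left = np.abs(times - tt[left])
        d_right = np.abs(tt[right] - times)
        # earlier detection wins ties (<=)
        pick = np.where(d_left <= d_right, left, right)
        dist = np.minimum(d_left, d_right)
        # a detection exactly dt/2 from two grid points belongs to the
        # earlier grid point (the one it follows), not the later one
        ok = (dist < half) | (tt[pick] - times == half)
        xy[ok, j, :] = pos[pick[ok]]
        valid[:, j] = ok
    return FrameSet(times=times, fish_ids=fish_ids, xy=xy, valid=valid, dt=float(dt))
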