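"""Frame timing, time-activity curves and the cumulative-sum transform.

Dynamic PET data are reconstructed into frames of varying duration (short
frames during the bolus passage, longer ones later).  All curve analysis in
this package is carried out on the frame *mid-times*.  The central transform
is the frame-spacing-weighted cumulative sum of a time-activity curve (TAC):

    TACsum[k] = sum_{i<=k} TAC[i] * w[i],   w[i] = mid[i+1] - mid[i]

which converts a noisy concentration curve (Bq/ml) into a smooth, nearly
monotone integral curve (Bq*s/ml).  Weighting by the mid-time spacing rather
than a constant keeps the summed curve free of kinks where the frame duration
changes; the last frame, which has no successor mid-time, is weighted by its
own duration (the consistent limit for uniform schedules).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "CumulativeCurve",
    "InvalidScheduleError",
    "TacFormatError",
    "build_schedule",
    "cumulative_sum",
    "frame_weights",
    "read_tac_table",
    "write_tac_table",
    "read_timing_sidecar",
]


class InvalidScheduleError(ValueError):
    """Raised for empty, overlapping or non-positive-duration frame timing."""


class TacFormatError(ValueError):
    """Raised when a TAC table on disk cannot be parsed."""


@dataclass(frozen=True)
class FrameSchedule:
    """Per-frame start times and durations, in seconds from scan start.

    Parameters
    ----------
    frame_start
        Start time of each frame (s), strictly increasing.
    frame_duration
        Duration of each frame (s), all positive.  Frames must not overlap.
    """

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)
        if start.ndim != 1 or dur.ndim != 1 or start.size != dur.size:
            raise InvalidScheduleError("frame_start and frame_duration must be 1-D and equal length")
        if start.size == 0:
            raise InvalidScheduleError("schedule has no frames")
        if not np.all(np.isfinite(start)) or not np.all(np.isfinite(dur)):
            raise InvalidScheduleError("non-finite frame timing")
        if np.any(dur <= 0):
            raise InvalidScheduleError("frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise InvalidScheduleError("frame starts must be strictly increasing")
        if np.any(start[1:] < start[:-1] + dur[:-1] - 1e-9):
            raise InvalidScheduleError("frames overlap")

    @property
    def n_frames(self) -> int:
        return int(self.frame_start.size)

    @property
    def mid_time(self) -> np.ndarray:
        """Temporal midpoint of each frame (s); the analysis time coordinate."""
        return self.frame_start + self.frame_duration / 2.0

    @property
    def end_time(self) -> float:
        """End of the last frame (s)."""
        return float(self.frame_start[-1] + self.frame_duration[-1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return (
            self.n_frames == other.n_frames
            and np.array_equal(self.frame_start, other.frame_start)
            and np.array_equal(self.frame_duration, other.frame_duration)
        )

    def __hash__(self) -> int:
        return hash((self.frame_start.tobytes(), self.frame_duration.tobytes()))


@dataclass(frozen=True)
class TimeActivityCurve:
    """Activity concentration (Bq/ml) sampled on a frame schedule.

    Negative values are permitted: iterative PET reconstruction noise can
    dip below zero, and downstream operations must not assume positivity.
    """

    schedule: FrameSchedule
    activity: np.ndarray

    def __post_init__(self) -> None:
        act = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "activity", act)
        if act.ndim != 1 or act.size != self.schedule.n_frames:
            raise ValueError("activity length must equal frame count")
        if not np.all(np.isfinite(act)):
            raise ValueError("activity values must be finite")

    def scaled(self, factor: float) -> "TimeActivityCurve":
        return TimeActivityCurve(self.schedule, self.activity * factor)


@dataclass(frozen=True)
class CumulativeCurve:
    """Frame-weighted running sum of a TAC (Bq*s/ml per frame)."""

    schedule: FrameSchedule
    values: np.ndarray
    plateau_corrected: bool = False

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size != self.schedule.n_frames:
            raise ValueError("values length must equal frame count")


def build_schedule(spec: Sequence[tuple[int, float]]) -> FrameSchedule:
    """Build a contiguous schedule from (frame_count, duration_s) blocks.

    Example: ``[(40, 1), (5, 4), (6, 10), (3, 20)]`` is the 54-frame, 180 s
    water schedule; ``[(40, 1), (10, 5), (15, 10), (6, 60)]`` the 71-frame,
    600 s FDG schedule.
    """
    if len(spec) == 0:
        raise InvalidScheduleError("empty schedule specification")
    durations: list[float] = []
    for count, dur in spec:
        if int(count) < 1:
            raise InvalidScheduleError(f"frame count must be >= 1, got {count}")
        if not (float(dur) > 0):
            raise InvalidScheduleError(f"frame duration must be positive, got {dur}")
        durations.extend([float(dur)] * int(count))
    dur_arr = np.asarray(durations)
    start = np.concatenate([[0.0], np.cumsum(dur_arr)[:-1]])
    return FrameSchedule(start, dur_arr)


def frame_weights(schedule: FrameSchedule) -> np.ndarray:
    """Cumulative-sum weight per frame: mid-time spacing, own duration for the last."""
    mid = schedule.mid_time
    w = np.empty(schedule.n_frames)
    w[:-1] = np.diff(mid)
    w[-1] = schedule.frame_duration[-1]
    return w


def cumulative_sum(tac: TimeActivityCurve) -> CumulativeCurve:
    """Cumulatively sum a TAC with mid-time-spacing weights.

    For a constant TAC on any schedule the result is a single straight ramp
    with no step where the frame duration changes.
    """
    values = np.cumsum(tac.activity * frame_weights(tac.schedule))
    return CumulativeCurve(tac.schedule, values)


_TAC_COLUMNS = ("frame_start", "frame_duration", "activity")


def read_tac_table(path: str | Path) -> TimeActivityCurve:
    """Read a TAC from a delimited table.

    The table must have a header row with columns ``frame_start``,
    ``frame_duration`` and ``activity`` (seconds, seconds, Bq/ml); comma or
    tab delimiters are auto-detected.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TacFormatError(f"{path}: cannot parse table ({exc})") from exc
    missing = [c for c in _TAC_COLUMNS if c not in df.columns]
    if missing:
        raise TacFormatError(f"{path}: missing columns {missing}")
    for col in _TAC_COLUMNS:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise TacFormatError(f"{path}: non-numeric value in column {col!r} at line {line}")
        if df[col].isna().any():
            line = int(df[col].isna().idxmax()) + 2
            raise TacFormatError(f"{path}: missing value in column {col!r} at line {line}")
    schedule = FrameSchedule(df["frame_start"].to_numpy(float), df["frame_duration"].to_numpy(float))
    return TimeActivityCurve(schedule, df["activity"].to_numpy(float))


def write_tac_table(tac: TimeActivityCurve, path: str | Path) -> None:
    """Write a TAC as CSV with full float precision (round-trips exactly)."""
    df = pd.DataFrame(
        {
            "frame_start": tac.schedule.frame_start,
            "frame_duration": tac.schedule.frame_duration,
            "activity": tac.activity,
        }
    )
    df.to_csv(path, index=False)


def read_timing_sidecar(path: str | Path) -> FrameSchedule:
    """Read frame timing from a BIDS-PET style JSON sidecar.

    Expects arrays ``FrameTimesStart`` and ``FrameDuration`` in seconds.
    """
    with open(path) as fh:
        meta = json.load(fh)
    try:
        start = np.asarray(meta["FrameTimesStart"], dtype=float)
        dur = np.asarray(meta["FrameDuration"], dtype=float)
    except KeyError as exc:
        raise TacFormatError(f"{path}: missing {exc} in timing sidecar") from exc
    return FrameSchedule(start, dur)
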