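"""Gaze-log domain types and I/O.

Coordinate conventions
----------------------
Two pixel coordinate systems appear throughout:

* **screen coordinates** — raw eye-tracker output, origin at the top-left of
  the display;
* **frame coordinates** — origin at the top-left of the video frame, x
  rightward, y downward, continuous pixel units.

The clip is shown centred on the display, so the two differ by a constant
offset. Frame indices are 1-based in every public interface (frame 1 is the
first presented frame); internally tracks store one row per frame in a
``(n_frames, 2)`` float array with ``NaN`` marking missing frames.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, SchemaError

__all__ = [
    "PresentationCondition",
    "RawGazeRecord",
    "ScreenGeometry",
    "GazeTrack",
    "screen_to_frame",
    "frame_to_screen",
    "align_gaze_to_frames",
    "read_gaze_csv",
    "write_gaze_csv",
    "read_track_csv",
    "write_track_csv",
]


class PresentationCondition(str, enum.Enum):
    """The four presentation-sequence manipulations of a source clip."""

    NORMAL_VIDEO = "normal_video"
    REVERSED_VIDEO = "reversed_video"
    NORMAL_IMAGES = "normal_images"
    RANDOMISED_IMAGES = "randomised_images"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Conditions in canonical order.
CONDITIONS = tuple(PresentationCondition)


@dataclass(frozen=True)
class RawGazeRecord:
    """One raw eye-tracker sample.

    ``t`` is seconds from clip onset; ``x_screen``/``y_screen`` are display
    pixels; ``valid`` is the tracker-reported validity flag (False during
    blinks or track loss).
    """

    observer_id: str
    clip_id: str
    condition: PresentationCondition
    t: float
    x_screen: float
    y_screen: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.t < 0:
            raise InputError(f"negative sample time {self.t!r}")


@dataclass(frozen=True)
class ScreenGeometry:
    """Placement of the video frame on the display.

    The study geometry is a 720x404 clip centred on a 1024x768 screen, giving
    offsets (152, 182).
    """

    screen_w: int
    screen_h: int
    frame_w: int
    frame_h: int
    offset_x: float
    offset_y: float

    def __post_init__(self) -> None:
        if self.frame_w > self.screen_w or self.frame_h > self.screen_h:
            raise ConfigurationError(
                "frame larger than screen: "
                f"{self.frame_w}x{self.frame_h} on {self.screen_w}x{self.screen_h}"
            )
        if self.offset_x < 0 or self.offset_y < 0:
            raise ConfigurationError(
                f"negative placement offsets ({self.offset_x}, {self.offset_y})"
            )

    @classmethod
    def centered(
        cls, screen_w: int, screen_h: int, frame_w: int, frame_h: int
    ) -> "ScreenGeometry":
        """Geometry for a frame displayed centred on the screen."""
        return cls(
            screen_w=screen_w,
            screen_h=screen_h,
            frame_w=frame_w,
            frame_h=frame_h,
            offset_x=(screen_w - frame_w) / 2,
            offset_y=(screen_h - frame_h) / 2,
        )


#: The study's display geometry: 720x404 clips centred on a 1024x768 monitor.
STUDY_GEOMETRY = ScreenGeometry.centered(1024, 768, 720, 404)


@dataclass
class GazeTrack:
    """One source's gaze point per presented frame, in frame coordinates.

    ``source_id`` names an observer or a predictor. ``xy`` has shape
    ``(n_frames, 2)``; missing frames are ``NaN`` in both columns.
    """

    source_id: str
    clip_id: str
    condition: PresentationCondition
    xy: np.ndarray
    frame_w: int
    frame_h: int

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise InputError(f"track array must be (n, 2), got {self.xy.shape}")
        ok = self.xy[~np.isnan(self.xy).any(axis=1)]
        if ok.size and (
            (ok[:, 0] < 0).any()
            or (ok[:, 0] >= self.frame_w).any()
            or (ok[:, 1] < 0).any()
            or (ok[:, 1] >= self.frame_h).any()
        ):
            raise InputError("gaze point outside the frame extent")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask, True where the frame has no gaze point."""
        return np.isnan(self.xy).any(axis=1)

    def point(self, frame: int) -> tuple[float, float] | None:
        """Gaze point at 1-based presented frame ``frame``, None if missing."""
        p = self.xy[frame - 1]
        if np.isnan(p).any():
            return None
        return float(p[0]), float(p[1])


def screen_to_frame(
    p: tuple[float, float], geom: ScreenGeometry
) -> tuple[float, float] | None:
    """Map a screen point into frame coordinates; None if off the video area."""
    x = p[0] - geom.offset_x
    y = p[1] - geom.offset_y
    if not (0 <= x < geom.frame_w and 0 <= y < geom.frame_h):
        return None
    return (x, y)


def frame_to_screen(p: tuple[float, float], geom: ScreenGeometry) -> tuple[float, float]:
    """Inverse of :func:`screen_to_frame` on in-frame points."""
    return (p[0] + geom.offset_x, p[1] + geom.offset_y)


def align_gaze_to_frames(
    records: Sequence[RawGazeRecord],
    fps: float,
    n_frames: int,
    geom: ScreenGeometry,
    *,
    source_id: str | None = None,
    clip_id: str | None = None,
    condition: PresentationCondition | None = None,
) -> GazeTrack:
    """Reduce raw tracker samples to one gaze point per presented frame.

    Presented frame k (1-based) covers the half-open window
    ``[(k-1)/fps, k/fps)``, so every sample belongs to exactly one frame. The
    frame's point is the arithmetic mean of all valid, in-frame samples in its
    window; a window with none is MISSING. Samples mapping outside the video
    area are treated as invalid for their window.
    """
    if fps <= 0:
        raise ConfigurationError(f"fps must be positive, got {fps}")
    if n_frames < 1:
        raise ConfigurationError(f"n_frames must be >= 1, got {n_frames}")

    if records:
        meta = records[0]
        source_id = source_id or meta.observer_id
        clip_id = clip_id or meta.clip_id
        condition = condition or meta.condition
        t = np.array([r.t for r in records])
        if (np.diff(t) < 0).any():
            raise InputError("raw gaze samples are not sorted by time")
    else:
        source_id = source_id or "unknown"
        clip_id = clip_id or "unknown"
        condition = condition or PresentationCondition.NORMAL_VIDEO

    sums = np.zeros((n_frames, 2))
    counts = np.zeros(n_frames, dtype=int)
    for r in records:
        if not r.valid:
            continue
        p = screen_to_frame((r.x_screen, r.y_screen), geom)
        if p is None:
            continue
        k = int(np.floor(r.t * fps))  # 0-based window index
        if 0 <= k < n_frames:
            sums[k] += p
            counts[k] += 1

    xy = np.full((n_frames, 2), np.nan)
    has = counts > 0
    xy[has] = sums[has] / counts[has, None]
    return GazeTrack(
        source_id=source_id,
        clip_id=clip_id,
        condition=condition,
        xy=xy,
        frame_w=geom.frame_w,
        frame_h=geom.frame_h,
    )


# ---------------------------------------------------------------------------
# CSV I/O
#
# Gaze CSV (one row per raw sample):
#   observer_id,clip_id,condition,t_sec,x_screen,y_screen,valid
# Frame-track CSV (one row per presented frame):
#   source_id,clip_id,condition,frame,x,y,missing

_GAZE_COLUMNS = ["observer_id", "clip_id", "condition", "t_sec", "x_screen", "y_screen", "valid"]
_TRACK_COLUMNS = ["source_id", "clip_id", "condition", "frame", "x", "y", "missing"]


def _check_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    raise InputError(f"cannot parse boolean value {v!r}")


def read_gaze_csv(path) -> list[RawGazeRecord]:
    """Read raw gaze samples from the gaze CSV schema."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(df, _GAZE_COLUMNS, path)
    records: list[RawGazeRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        try:
            records.append(
                RawGazeRecord(
                    observer_id=row.observer_id,
                    clip_id=row.clip_id,
                    condition=PresentationCondition(row.condition),
                    t=float(row.t_sec),
                    x_screen=float(row.x_screen),
                    y_screen=float(row.y_screen),
                    valid=_parse_bool(row.valid),
                )
            )
        except (ValueError, InputError) as exc:
            raise InputError(f"{path}: line {i}: {exc}") from exc
    return records


def write_gaze_csv(records: Sequence[RawGazeRecord], path) -> None:
    """Write raw gaze samples; full float precision so read(write(x)) == x."""
    df = pd.DataFrame(
        {
            "observer_id": [r.observer_id for r in records],
            "clip_id": [r.clip_id for r in records],
            "condition": [r.condition.value for r in records],
            "t_sec": [repr(float(r.t)) for r in records],
            "x_screen": [repr(float(r.x_screen)) for r in records],
            "y_screen": [repr(float(r.y_screen)) for r in records],
            "valid": [r.valid for r in records],
        },
        columns=_GAZE_COLUMNS,
    )
    df.to_csv(path, index=False)


def write_track_csv(tracks: Sequence[GazeTrack], path) -> None:
    """Write frame-indexed tracks in the frame-track CSV schema."""
    rows = []
    for tr in tracks:
        miss = tr.missing
        for k in range(tr.n_frames):
            rows.append(
                (
                    tr.source_id,
                    tr.clip_id,
                    tr.condition.value,
                    k + 1,
                    "" if miss[k] else repr(float(tr.xy[k, 0])),
                    "" if miss[k] else repr(float(tr.xy[k, 1])),
                    bool(miss[k]),
                )
            )
    pd.DataFrame(rows, columns=_TRACK_COLUMNS).to_csv(path, index=False)


def read_track_csv(path, frame_w: int, frame_h: int) -> list[GazeTrack]:
    """Read frame-indexed tracks; the frame extent is not stored in the file
    and must be supplied."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(df, _TRACK_COLUMNS, path)
    tracks: list[GazeTrack] = []
    for (src, clip, cond), grp in df.groupby(
        ["source_id", "clip_id", "condition"], sort=False
    ):
        frames = grp["frame"].astype(int).to_numpy()
        n = frames.max()
        xy = np.full((n, 2), np.nan)
        for _, row in grp.iterrows():
            if _parse_bool(row["missing"]):
                continue
            k = int(row["frame"]) - 1
            xy[k] = (float(row["x"]), float(row["y"]))
        tracks.append(
            GazeTrack(
                source_id=src,
                clip_id=clip,
                condition=PresentationCondition(cond),
                xy=xy,
                frame_w=frame_w,
                frame_h=frame_h,
            )
        )
    return tracks
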