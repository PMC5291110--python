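"""Presentation-sequence manipulations of a source clip.

A 3-s, 30-fps clip (90 frames) is presented in four conditions:

* ``normal_video`` — original order, frames 1..90;
* ``reversed_video`` — time-reversed, frames 90..1;
* ``normal_images`` — six stills sampled at frames 1, 16, 31, 46, 61, 76,
  shown in original order for 500 ms (15 presented frames) each;
* ``randomised_images`` — the same six stills in a seeded random order.

Every manipulation preserves the presented duration (N frames) and is
described by a :class:`SequenceMap` giving, for each presented frame, the
source frame whose content is on screen. That map is the single source of
truth for content alignment when gaze in different conditions is compared on
identical frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .gaze_data import CONDITIONS, PresentationCondition

__all__ = [
    "Clip",
    "SequenceMap",
    "sample_still_indices",
    "make_sequence",
    "condition_count",
    "generate_all_sequences",
    "read_clip_dir",
    "write_clip_dir",
]

#: Per-still display duration used in the study, milliseconds.
DEFAULT_STILL_MS = 500.0
#: Number of stills sampled for the image conditions.
N_STILLS = 6
#: Source-frame stride between consecutive stills for a 90-frame clip.
STUDY_STILL_STRIDE = 15


@dataclass
class Clip:
    """An ordered frame stack. ``frames`` is ``(n, h, w)`` grayscale or
    ``(n, h, w, 3)`` RGB; frame indices are 1-based in all interfaces."""

    clip_id: str
    frames: np.ndarray
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ConfigurationError(
                f"frames must be (n, h, w[, 3]), got shape {self.frames.shape}"
            )
        if self.fps <= 0:
            raise ConfigurationError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_h(self) -> int:
        return self.frames.shape[1]

    @property
    def frame_w(self) -> int:
        return self.frames.shape[2]

    def frame(self, k: int) -> np.ndarray:
        """Raster of 1-based frame ``k``."""
        return self.frames[k - 1]


@dataclass
class SequenceMap:
    """Presented-frame -> source-frame alignment for one condition.

    ``mapping[k-1]`` is the 1-based source frame displayed as presented frame
    k. ``still_order`` lists, for image conditions, the sampled source frames
    in display order.
    """

    condition: PresentationCondition
    mapping: np.ndarray
    still_order: list[int] | None = None

    def __post_init__(self) -> None:
        self.mapping = np.asarray(self.mapping, dtype=int)
        if self.mapping.ndim != 1 or self.mapping.size == 0:
            raise ConfigurationError("mapping must be a non-empty 1-D index array")

    @property
    def n_frames(self) -> int:
        return self.mapping.size

    def source_frame(self, presented: int) -> int:
        """1-based source frame shown as 1-based presented frame."""
        return int(self.mapping[presented - 1])

    @classmethod
    def identity(cls, n_frames: int) -> "SequenceMap":
        return cls(PresentationCondition.NORMAL_VIDEO, np.arange(1, n_frames + 1))

    @classmethod
    def reverse(cls, n_frames: int) -> "SequenceMap":
        return cls(PresentationCondition.REVERSED_VIDEO, np.arange(n_frames, 0, -1))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "condition": self.condition.value,
                "presented_frame": np.arange(1, self.n_frames + 1),
                "source_frame": self.mapping,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SequenceMap":
        df = pd.read_csv(path)
        cond = PresentationCondition(df["condition"].iloc[0])
        df = df.sort_values("presented_frame")
        return cls(cond, df["source_frame"].to_numpy())


def sample_still_indices(
    n_frames: int, n_stills: int = N_STILLS, stride: int | None = STUDY_STILL_STRIDE
) -> list[int]:
    """Source frames sampled as stills for the image conditions.

    The default is the study rule: six stills starting at frame 1 with a
    stride of 15 (frames 1, 16, 31, 46, 61, 76 of a 90-frame clip), which
    requires at least ``1 + (n_stills-1)*stride`` frames. Passing
    ``stride=None`` spreads the stills over clips of other lengths with
    ``stride = round(n_frames / n_stills)``.
    """
    if n_stills < 1:
        raise ConfigurationError(f"n_stills must be >= 1, got {n_stills}")
    if stride is None:
        stride = int(round(n_frames / n_stills))
        if stride < 1:
            raise ConfigurationError(
                f"clip of {n_frames} frames too short for {n_stills} stills"
            )
    indices = [1 + i * stride for i in range(n_stills)]
    if indices[-1] > n_frames:
        raise ConfigurationError(
            f"clip has {n_frames} frames but still sampling needs at least "
            f"{indices[-1]} (n_stills={n_stills}, stride={stride})"
        )
    return indices


def _still_mapping(
    n_frames: int, fps: float, still_ms: float, order: list[int]
) -> np.ndarray:
    per_still = still_ms * fps / 1000.0
    if abs(per_still - round(per_still)) > 1e-9:
        raise ConfigurationError(
            f"still duration {still_ms} ms is not a whole number of frames at {fps} fps"
        )
    per_still = int(round(per_still))
    if per_still * len(order) != n_frames:
        raise ConfigurationError(
            f"{len(order)} stills x {per_still} frames != clip length {n_frames}"
        )
    return np.repeat(np.asarray(order, dtype=int), per_still)


def make_sequence(
    clip: Clip,
    condition: PresentationCondition,
    still_ms: float = DEFAULT_STILL_MS,
    rng_seed: int | None = None,
) -> tuple[Clip, SequenceMap]:
    """Build the presented clip and its content-alignment map for one condition.

    The randomised image order is a uniform permutation drawn from a seeded
    generator, redrawn if it equals the normal display order, so "randomised"
    always differs from "normal_images" (with 6! = 720 orders the redraw bias
    is negligible and determinism under a fixed seed is preserved).
    """
    n = clip.n_frames
    if condition == PresentationCondition.NORMAL_VIDEO:
        seq_map = SequenceMap.identity(n)
    elif condition == PresentationCondition.REVERSED_VIDEO:
        seq_map = SequenceMap.reverse(n)
    elif condition in (
        PresentationCondition.NORMAL_IMAGES,
        PresentationCondition.RANDOMISED_IMAGES,
    ):
        stills = sample_still_indices(n)
        if condition == PresentationCondition.RANDOMISED_IMAGES:
            rng = np.random.default_rng(rng_seed)
            order = list(stills)
            while True:
                order = [stills[i] for i in rng.permutation(len(stills))]
                if order != stills or len(stills) == 1:
                    break
        else:
            order = list(stills)
        seq_map = SequenceMap(condition, _still_mapping(n, clip.fps, still_ms, order), order)
    else:  # pragma: no cover - enum is closed
        raise ConfigurationError(f"unknown condition {condition!r}")

    presented = Clip(
        clip_id=f"{clip.clip_id}",
        frames=clip.frames[seq_map.mapping - 1],
        fps=clip.fps,
    )
    return presented, seq_map


def condition_count(n_clips: int) -> int:
    """Number of presented sequences generated from ``n_clips`` source clips
    (30 source clips -> 120)."""
    if n_clips < 1:
        raise ConfigurationError(f"n_clips must be >= 1, got {n_clips}")
    return n_clips * len(CONDITIONS)


def generate_all_sequences(
    clip: Clip, still_ms: float = DEFAULT_STILL_MS, rng_seed: int | None = None
) -> dict[PresentationCondition, tuple[Clip, SequenceMap]]:
    """All four presented sequences for one source clip."""
    return {
        cond: make_sequence(clip, cond, still_ms=still_ms, rng_seed=rng_seed)
        for cond in CONDITIONS
    }


def write_clip_dir(clip: Clip, directory) -> None:
    """Write a clip as a directory of numbered PNG frames plus a metadata file."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k in range(1, clip.n_frames + 1):
        iio.imwrite(directory / f"frame_{k:04d}.png", clip.frame(k).astype(np.uint8))
    (directory / "clip.txt").write_text(f"clip_id={clip.clip_id}\nfps={clip.fps}\n")


def read_clip_dir(directory) -> Clip:
    """Read a clip written by :func:`write_clip_dir` (or any directory of
    numbered PNG frames)."""
    import imageio.v3 as iio

    directory = Path(directory)
    paths = sorted(directory.glob("frame_*.png"))
    if not paths:
        raise InputError(f"{directory}: no frame_*.png files found")
    frames = np.stack([iio.imread(p) for p in paths])
    clip_id, fps = directory.name, 30.0
    meta = directory / "clip.txt"
    if meta.exists():
        for line in meta.read_text().splitlines():
            key, _, val = line.partition("=")
            if key == "clip_id":
                clip_id = val
            elif key == "fps":
                fps = float(val)
    return Clip(clip_id=clip_id, frames=frames, fps=fps)
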