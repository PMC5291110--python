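"""Reference gaze predictors and adapters for external saliency output.

Published attention models are not reimplemented here; any external tool can
deposit per-frame saliency rasters (numbered grayscale images) or a
frame-track CSV and be scored like any other predictor. The built-in
predictors are deliberately simple baselines:

* ``center_predictor`` — the frame centre every frame (the central-bias
  reference);
* ``random_predictor`` — i.i.d. uniform points (the chance reference);
* ``motion_energy_predictor`` — argmax of smoothed absolute frame
  differencing, a minimal content-dependent stand-in for the motion channel
  dynamic-saliency models share.

All predictors are pure functions of the presented clip (plus seed). That
purity is what makes them — like published saliency models — blind to
presentation-sequence manipulations: at content-aligned frames they emit
identical predictions whatever the display order.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, InputError
from .gaze_data import GazeTrack, PresentationCondition
from .sequencing import Clip

__all__ = [
    "saliency_argmax",
    "saliency_centroid",
    "center_predictor",
    "random_predictor",
    "motion_energy_predictor",
    "read_saliency_dir",
]

#: Box-smoothing radius (pixels) for the motion-energy predictor.
DEFAULT_SMOOTHING_RADIUS = 8


def _track(clip: Clip, source_id: str, xy: np.ndarray,
           condition: PresentationCondition = PresentationCondition.NORMAL_VIDEO,
           ) -> GazeTrack:
    return GazeTrack(
        source_id=source_id,
        clip_id=clip.clip_id,
        condition=condition,
        xy=xy,
        frame_w=clip.frame_w,
        frame_h=clip.frame_h,
    )


def _argmax_point(sal: np.ndarray) -> tuple[float, float] | None:
    """Location of the maximum; ties broken row-major (smallest y, then x).
    None for an all-zero (unsalient) frame."""
    if (sal < 0).any():
        raise InputError("saliency maps must be non-negative")
    if not (sal > 0).any():
        return None
    flat = int(np.argmax(sal))  # first occurrence = row-major tie rule
    y, x = np.unravel_index(flat, sal.shape)
    return (float(x), float(y))


def _centroid_point(sal: np.ndarray) -> tuple[float, float] | None:
    if (sal < 0).any():
        raise InputError("saliency maps must be non-negative")
    total = sal.sum(dtype=float)
    if total <= 0:
        return None
    h, w = sal.shape
    ys, xs = np.mgrid[0:h, 0:w]
    return (float((xs * sal).sum() / total), float((ys * sal).sum() / total))


def _maps_to_track(
    clip: Clip, maps: Sequence[np.ndarray], source_id: str, point_rule
) -> GazeTrack:
    if len(maps) != clip.n_frames:
        raise InputError(
            f"{len(maps)} saliency maps for a {clip.n_frames}-frame clip"
        )
    xy = np.full((clip.n_frames, 2), np.nan)
    for k, sal in enumerate(maps):
        sal = np.asarray(sal, dtype=float)
        if sal.shape != (clip.frame_h, clip.frame_w):
            raise InputError(
                f"map {k + 1} has shape {sal.shape}, frame is "
                f"{clip.frame_h}x{clip.frame_w}"
            )
        p = point_rule(sal)
        if p is not None:
            xy[k] = p
    return _track(clip, source_id, xy)


def saliency_argmax(
    clip: Clip, maps: Sequence[np.ndarray], source_id: str = "saliency_argmax"
) -> GazeTrack:
    """Predicted track from per-frame saliency maps via the map maximum.

    Ties break to the smallest y then smallest x (row-major first
    occurrence); an all-zero frame yields a MISSING prediction.
    """
    return _maps_to_track(clip, maps, source_id, _argmax_point)


def saliency_centroid(
    clip: Clip, maps: Sequence[np.ndarray], source_id: str = "saliency_centroid"
) -> GazeTrack:
    """Alternative map->point rule: saliency-weighted centroid."""
    return _maps_to_track(clip, maps, source_id, _centroid_point)


def center_predictor(clip: Clip, source_id: str = "center") -> GazeTrack:
    """Predict the frame centre on every frame."""
    xy = np.tile([clip.frame_w / 2.0, clip.frame_h / 2.0], (clip.n_frames, 1))
    return _track(clip, source_id, xy)


def random_predictor(
    clip: Clip, rng_seed: int | None = None, source_id: str = "random"
) -> GazeTrack:
    """Predict i.i.d. uniform points over the frame; seed-reproducible."""
    rng = np.random.default_rng(rng_seed)
    xy = rng.uniform((0.0, 0.0), (clip.frame_w, clip.frame_h), size=(clip.n_frames, 2))
    return _track(clip, source_id, xy)


def _luminance(frames: np.ndarray) -> np.ndarray:
    if frames.ndim == 4:
        return frames.astype(np.float32).mean(axis=3)
    return frames.astype(np.float32)


def motion_energy_predictor(
    clip: Clip,
    smoothing_radius: int = DEFAULT_SMOOTHING_RADIUS,
    source_id: str = "motion_energy",
) -> GazeTrack:
    """Predict the peak of smoothed inter-frame luminance change.

    For frame k >= 2 the prediction is the argmax of the box-smoothed
    absolute luminance difference |frame_k - frame_{k-1}| (box of side
    2*radius+1); frame 1 inherits frame 2's prediction. Frames with zero
    difference (static content) yield MISSING predictions.
    """
    if clip.n_frames < 2:
        raise InputError("motion-energy prediction needs at least 2 frames")
    lum = _luminance(clip.frames)
    size = 2 * int(smoothing_radius) + 1
    xy = np.full((clip.n_frames, 2), np.nan)
    for k in range(1, clip.n_frames):
        diff = np.abs(lum[k] - lum[k - 1])
        if size > 1:
            # separable sliding sums can go epsilon-negative in float
            diff = np.maximum(ndimage.uniform_filter(diff, size=size, mode="constant"), 0.0)
        p = _argmax_point(diff)
        if p is not None:
            xy[k] = p
    xy[0] = xy[1]
    return _track(clip, source_id, xy)


def read_saliency_dir(directory) -> list[np.ndarray]:
    """Read a directory of numbered grayscale images as saliency maps."""
    import imageio.v3 as iio

    paths = sorted(Path(directory).glob("*.png"))
    if not paths:
        raise InputError(f"{directory}: no .png saliency maps found")
    maps = []
    for p in paths:
        m = np.asarray(iio.imread(p), dtype=float)
        if m.ndim == 3:
            m = m.mean(axis=2)
        maps.append(m)
    return maps
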