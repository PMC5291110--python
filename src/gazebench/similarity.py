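"""The frame-based similarity score and the protocols built on it.

For one video frame, let (x0, y0) be the benchmark gaze location — the mean
of the observers' gaze points — and (x1, y1) a predicted (or held-out) gaze
location. With

    D_f  = Euclidean distance from the prediction to the benchmark,
    D̄_i = Euclidean distance of contributing observer i from the benchmark,
    D̄   = mean of the D̄_i,

the frame's similarity score is

    S = D̄ / (D̄ + D_f),

a unitless quantity in [0, 1]: 1 when the prediction coincides with the
benchmark, 0.5 when the prediction errs by exactly the cohort's own
dispersion, approaching 0 as the error dwarfs it. A clip's score is the mean
of S over its scorable frames. Because S is a ratio of distances it is
invariant to translating or uniformly rescaling all coordinates, which makes
scores comparable across stimulus sizes and cohorts.

Degenerate cohort (D̄ = 0, possible with few or identical observers): the
formula's own limit is used — S = 1 if D_f = 0 (perfect prediction of a
perfectly concordant cohort), else S = 0.

On top of the frame score this module implements the leave-one-out
inter-observer protocol (the human baseline), the uniform-random chance
baseline, content-aligned cross-sequence similarity, and the central
fixation bias summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InputError
from .gaze_data import GazeTrack, PresentationCondition
from .sequencing import SequenceMap

__all__ = [
    "BenchmarkTrack",
    "FrameSimilarity",
    "ClipSimilarity",
    "CentralBiasSummary",
    "ChanceBaseline",
    "euclidean_distance",
    "frame_similarity",
    "build_benchmark",
    "clip_similarity",
    "interobserver_similarity",
    "chance_baseline",
    "cross_sequence_similarity",
    "central_bias",
]

#: Repetitions used for the chance baseline.
DEFAULT_CHANCE_REPS = 100

_OK = "OK"
_SKIPPED = "SKIPPED_MISSING"

#: Distances below this many pixels are treated as exactly zero, so the
#: degenerate-cohort rule is not defeated by floating-point rounding when
#: averaging identical coordinates (1e-9 px is far below any physical gaze
#: or display precision).
ZERO_DISTANCE_EPS = 1e-9


def euclidean_distance(p: Sequence[float], q: Sequence[float]) -> float:
    """Euclidean distance between two frame points, in pixels."""
    return float(np.hypot(p[0] - q[0], p[1] - q[1]))


def frame_similarity(dbar: float, d_f: float) -> float:
    """Similarity score S = D̄/(D̄ + D_f) for one frame.

    ``dbar`` is the cohort's mean distance from the benchmark, ``d_f`` the
    prediction's distance from it; both in pixels, both >= 0.
    """
    if dbar < 0 or d_f < 0:
        raise InputError(f"distances must be non-negative, got D̄={dbar}, D_f={d_f}")
    if dbar <= ZERO_DISTANCE_EPS:
        return 1.0 if d_f <= ZERO_DISTANCE_EPS else 0.0
    return dbar / (dbar + d_f)


def _frame_similarity_vec(dbar: np.ndarray, d_f: np.ndarray) -> np.ndarray:
    """Vectorised :func:`frame_similarity` (no NaN handling)."""
    s = np.empty_like(dbar, dtype=float)
    zero = dbar <= ZERO_DISTANCE_EPS
    s[zero] = np.where(d_f[zero] <= ZERO_DISTANCE_EPS, 1.0, 0.0)
    nz = ~zero
    s[nz] = dbar[nz] / (dbar[nz] + d_f[nz])
    return s


@dataclass
class BenchmarkTrack:
    """Per-frame cross-observer mean gaze with the cohort's dispersion.

    ``xy`` is the benchmark point per frame (NaN where no observer
    contributed); ``dists`` is the (n_frames, n_observers) matrix of each
    contributing observer's distance from the benchmark (NaN where the
    observer was missing); ``dbar`` its per-frame mean; ``n_observers`` the
    per-frame count of contributors.
    """

    clip_id: str
    condition: PresentationCondition
    xy: np.ndarray
    dbar: np.ndarray
    dists: np.ndarray
    n_observers: np.ndarray
    frame_w: int
    frame_h: int
    observer_ids: list[str] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.xy).any(axis=1)


def build_benchmark(tracks: Sequence[GazeTrack]) -> BenchmarkTrack:
    """Average one clip+condition's observer tracks into a benchmark.

    Per frame the benchmark point is the mean of the non-missing observer
    points; D̄_i is each contributing observer's distance from that point and
    D̄ their mean. Frames with zero contributors are MISSING.
    """
    if not tracks:
        raise InputError("cannot build a benchmark from an empty track set")
    n = tracks[0].n_frames
    clip_id, cond = tracks[0].clip_id, tracks[0].condition
    for tr in tracks:
        if tr.n_frames != n:
            raise InputError(
                f"track length mismatch: {tr.source_id} has {tr.n_frames} frames, expected {n}"
            )
        if tr.clip_id != clip_id or tr.condition != cond:
            raise InputError(
                f"track {tr.source_id} is for {tr.clip_id}/{tr.condition}, "
                f"expected {clip_id}/{cond}"
            )

    stack = np.stack([tr.xy for tr in tracks])  # (n_obs, n_frames, 2)
    with np.errstate(invalid="ignore"):
        bench = np.nanmean(stack, axis=0)  # all-NaN frames stay NaN
    dists = np.linalg.norm(stack - bench[None, :, :], axis=2).T  # (n_frames, n_obs)
    with np.errstate(invalid="ignore"):
        dbar = np.nanmean(dists, axis=1)
    n_obs = (~np.isnan(dists)).sum(axis=1)
    return BenchmarkTrack(
        clip_id=clip_id,
        condition=cond,
        xy=bench,
        dbar=dbar,
        dists=dists,
        n_observers=n_obs,
        frame_w=tracks[0].frame_w,
        frame_h=tracks[0].frame_h,
        observer_ids=[tr.source_id for tr in tracks],
    )


@dataclass(frozen=True)
class FrameSimilarity:
    """Score of one frame: distances, S, and whether the frame was scorable."""

    frame: int  # 1-based
    d_f: float
    dbar: float
    s: float
    status: str  # OK | SKIPPED_MISSING


@dataclass
class ClipSimilarity:
    """Clip-level similarity of one prediction source against a benchmark.

    ``mean_s`` is None when no frame was scorable (an explicitly unscorable
    clip, not a number).
    """

    source_id: str
    clip_id: str
    condition: PresentationCondition
    mean_s: float | None
    n_scored: int
    n_skipped: int
    frames: list[FrameSimilarity] = field(default_factory=list, repr=False)

    @property
    def scorable(self) -> bool:
        return self.mean_s is not None


def _score_frames(
    dbar: np.ndarray, d_f: np.ndarray, scorable: np.ndarray
) -> tuple[float | None, list[FrameSimilarity]]:
    frames: list[FrameSimilarity] = []
    svals = []
    for k in range(dbar.size):
        if scorable[k]:
            s = frame_similarity(float(dbar[k]), float(d_f[k]))
            frames.append(FrameSimilarity(k + 1, float(d_f[k]), float(dbar[k]), s, _OK))
            svals.append(s)
        else:
            frames.append(FrameSimilarity(k + 1, np.nan, np.nan, np.nan, _SKIPPED))
    return (float(np.mean(svals)) if svals else None), frames


def clip_similarity(bench: BenchmarkTrack, pred: GazeTrack) -> ClipSimilarity:
    """Score a prediction track against a benchmark, frame by frame.

    Frames where either the benchmark or the prediction is MISSING are
    skipped and excluded from the clip mean; their count is reported.
    """
    if pred.n_frames != bench.n_frames:
        raise InputError(
            f"prediction has {pred.n_frames} frames, benchmark {bench.n_frames}"
        )
    d_f = np.linalg.norm(pred.xy - bench.xy, axis=1)
    scorable = ~(bench.missing | pred.missing)
    mean_s, frames = _score_frames(bench.dbar, d_f, scorable)
    return ClipSimilarity(
        source_id=pred.source_id,
        clip_id=pred.clip_id,
        condition=pred.condition,
        mean_s=mean_s,
        n_scored=int(scorable.sum()),
        n_skipped=int((~scorable).sum()),
        frames=frames,
    )


def interobserver_similarity(tracks: Sequence[GazeTrack]) -> list[ClipSimilarity]:
    """All-except-one agreement: score each observer against the rest.

    For each observer the benchmark — and the normalising D̄ — is rebuilt
    from the remaining n-1 observers, so no observer normalises their own
    score; the observer's own track plays the prediction role. The mean of
    the returned clip scores is the human baseline, the empirical upper
    bound for model performance.
    """
    if len(tracks) < 2:
        raise InputError("leave-one-out agreement needs at least 2 observers")
    out = []
    for i, held_out in enumerate(tracks):
        bench = build_benchmark([tr for j, tr in enumerate(tracks) if j != i])
        out.append(clip_similarity(bench, held_out))
    return out


@dataclass
class ChanceBaseline:
    """Similarity of uniformly random gaze against a benchmark.

    One repetition draws an independent uniform pixel of the video frame for
    every frame and scores that track like a prediction; ``per_rep`` holds
    each repetition's clip score.
    """

    clip_id: str
    condition: PresentationCondition
    mean_s: float
    sd_s: float
    n_reps: int
    per_rep: np.ndarray = field(repr=False, default=None)


def chance_baseline(
    bench: BenchmarkTrack,
    n_reps: int = DEFAULT_CHANCE_REPS,
    rng_seed: int | None = None,
) -> ChanceBaseline:
    """Monte-Carlo chance level of the similarity score for one benchmark."""
    if n_reps < 1:
        raise InputError(f"n_reps must be >= 1, got {n_reps}")
    if bench.frame_w < 1 or bench.frame_h < 1:
        raise ConfigurationError(
            f"degenerate frame extent {bench.frame_w}x{bench.frame_h}"
        )
    rng = np.random.default_rng(rng_seed)
    n = bench.n_frames
    ok = ~bench.missing
    if not ok.any():
        raise InputError("benchmark has no scorable frames")
    scores = np.empty(n_reps)
    for rep in range(n_reps):
        # random "gaze" lands on the integer pixel grid of the video frame
        pts = rng.integers((0, 0), (bench.frame_w, bench.frame_h), size=(n, 2)).astype(float)
        d_f = np.linalg.norm(pts - bench.xy, axis=1)
        s = _frame_similarity_vec(bench.dbar[ok], d_f[ok])
        scores[rep] = s.mean()
    return ChanceBaseline(
        clip_id=bench.clip_id,
        condition=bench.condition,
        mean_s=float(scores.mean()),
        sd_s=float(scores.std(ddof=1)) if n_reps > 1 else 0.0,
        n_reps=n_reps,
        per_rep=scores,
    )


def cross_sequence_similarity(
    track_ref: GazeTrack,
    track_test: GazeTrack,
    map_test: SequenceMap,
    bench_ref: BenchmarkTrack,
) -> ClipSimilarity:
    """Similarity of one source's gaze in a manipulated condition to the same
    source's gaze on identical content in the normal sequence.

    Frames are aligned by content: presented frame k of the test condition is
    compared with the reference (normal-sequence) gaze at source frame
    ``map_test(k)``; D_f is the distance between the two gaze points and D̄
    comes from the normal-condition benchmark at that source frame. A high
    score therefore means the source allocates gaze to the same content the
    same way regardless of presentation order — which is exactly how
    content-pure predictors behave, and humans do not.
    """
    if map_test is None:
        raise InputError("cross-sequence similarity requires a sequence map")
    if track_test.n_frames != map_test.n_frames:
        raise InputError(
            f"test track has {track_test.n_frames} frames, map covers {map_test.n_frames}"
        )
    if track_ref.source_id != track_test.source_id:
        raise InputError(
            "cross-sequence comparison must use one source: "
            f"{track_ref.source_id!r} vs {track_test.source_id!r}"
        )
    src = map_test.mapping - 1  # 0-based source frames
    if src.max() >= track_ref.n_frames:
        raise InputError("sequence map addresses frames beyond the reference track")
    ref_xy = track_ref.xy[src]
    dbar = bench_ref.dbar[src]
    d_f = np.linalg.norm(track_test.xy - ref_xy, axis=1)
    scorable = ~(
        np.isnan(ref_xy).any(axis=1) | track_test.missing | np.isnan(dbar)
    )
    mean_s, frames = _score_frames(dbar, d_f, scorable)
    return ClipSimilarity(
        source_id=track_test.source_id,
        clip_id=track_test.clip_id,
        condition=track_test.condition,
        mean_s=mean_s,
        n_scored=int(scorable.sum()),
        n_skipped=int((~scorable).sum()),
        frames=frames,
    )


@dataclass
class CentralBiasSummary:
    """Mean distance of a source's gaze from the frame centre, in pixels.

    ``mean_dist`` is None for an all-missing (unscorable) track.
    """

    source_id: str
    clip_id: str
    condition: PresentationCondition
    mean_dist: float | None
    per_frame: np.ndarray = field(repr=False, default=None)

    @property
    def scorable(self) -> bool:
        return self.mean_dist is not None


def central_bias(
    track: GazeTrack, frame_w: int | None = None, frame_h: int | None = None
) -> CentralBiasSummary:
    """Central-fixation-bias summary: per-frame distance from the frame
    centre, averaged over non-missing frames."""
    frame_w = track.frame_w if frame_w is None else frame_w
    frame_h = track.frame_h if frame_h is None else frame_h
    centre = np.array([frame_w / 2.0, frame_h / 2.0])
    d = np.linalg.norm(track.xy - centre, axis=1)
    ok = ~track.missing
    return CentralBiasSummary(
        source_id=track.source_id,
        clip_id=track.clip_id,
        condition=track.condition,
        mean_dist=float(d[ok].mean()) if ok.any() else None,
        per_frame=d,
    )
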