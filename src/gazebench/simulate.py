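"""Synthetic clips and observer cohorts for end-to-end testing.

The generator emulates the statistical structure the evaluation pipeline
assumes, without claiming visual realism:

* **Scenes** are i.i.d. luminance-noise backgrounds with one or more bright
  targets moving at constant velocity (the "travelling car" of a traffic
  clip, reduced to what the motion-energy predictor and a tracking observer
  can latch onto). The ground-truth trajectory is returned alongside the
  rendered frames.
* **Observers** mix target tracking with a central-bias attractor: per
  presented frame, gaze is a convex combination of the (lagged,
  content-aligned) target position and the frame centre plus central
  jitter, with isotropic gaze noise on top. Disrupting the presentation
  order multiplies the tracking weight by a per-condition penalty
  (reversed < randomised images < normal images by default, so time
  reversal disrupts tracking most), shifting gaze toward the centre.
* **Cohorts** draw each observer's parameters from configured
  distributions, giving heterogeneous but seed-reproducible populations.

Gaze is generated directly at frame rate (one point per presented frame);
:func:`emit_raw_samples` wraps a frame-rate track back into 50 Hz raw
tracker samples (screen coordinates, jittered positions, optional blinks)
to exercise the raw-to-frame alignment path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InputError
from .gaze_data import (
    CONDITIONS,
    GazeTrack,
    PresentationCondition,
    RawGazeRecord,
    ScreenGeometry,
    frame_to_screen,
)
from .sequencing import Clip, SequenceMap, generate_all_sequences

__all__ = [
    "TargetSpec",
    "SceneConfig",
    "ObserverModel",
    "CohortConfig",
    "CohortDataset",
    "generate_clip",
    "target_trajectory",
    "generate_gaze",
    "generate_cohort",
    "random_scene",
    "default_scenes",
    "emit_raw_samples",
    "estimate_central_bias_sd",
]

# Frame geometry of the emulated display protocol: 3-s, 30-fps, 720x404 clips.
DEFAULT_FRAME_W = 720
DEFAULT_FRAME_H = 404
DEFAULT_N_FRAMES = 90
DEFAULT_FPS = 30.0


@dataclass(frozen=True)
class TargetSpec:
    """One moving target: start centre (pixels), per-frame velocity
    (pixels/frame), square side (pixels) and luminance contrast above
    background."""

    start: tuple[float, float]
    velocity: tuple[float, float]
    size: float = 24.0
    contrast: float = 90.0


@dataclass
class SceneConfig:
    """Parameters of one synthetic clip."""

    clip_id: str
    targets: list[TargetSpec]
    frame_w: int = DEFAULT_FRAME_W
    frame_h: int = DEFAULT_FRAME_H
    n_frames: int = DEFAULT_N_FRAMES
    fps: float = DEFAULT_FPS
    noise_sd: float = 8.0
    background: float = 96.0

    def __post_init__(self) -> None:
        if not self.targets:
            raise ConfigurationError("a scene needs at least one target")
        for t in self.targets:
            traj = _trajectory(t, self.n_frames)
            half = t.size / 2.0
            if (
                (traj[:, 0] < half).any()
                or (traj[:, 0] > self.frame_w - half).any()
                or (traj[:, 1] < half).any()
                or (traj[:, 1] > self.frame_h - half).any()
            ):
                raise ConfigurationError(
                    f"target starting at {t.start} with velocity {t.velocity} "
                    f"leaves the {self.frame_w}x{self.frame_h} frame"
                )


def _trajectory(target: TargetSpec, n_frames: int) -> np.ndarray:
    k = np.arange(n_frames)[:, None]
    return np.asarray(target.start, dtype=float) + k * np.asarray(
        target.velocity, dtype=float
    )


def target_trajectory(cfg: SceneConfig, target_index: int = 0) -> np.ndarray:
    """Ground-truth centre of one target, shape (n_frames, 2), frame pixels.
    Row k is the position at 1-based source frame k+1."""
    return _trajectory(cfg.targets[target_index], cfg.n_frames)


def generate_clip(cfg: SceneConfig, rng_seed: int | None = None) -> tuple[Clip, np.ndarray]:
    """Render a scene; returns the clip and the primary target's trajectory.

    Frames are uint8 luminance: i.i.d. Gaussian background noise with the
    targets drawn as uniform bright squares at their per-frame positions.
    """
    rng = np.random.default_rng(rng_seed)
    frames = rng.standard_normal(
        (cfg.n_frames, cfg.frame_h, cfg.frame_w), dtype=np.float32
    )
    frames *= cfg.noise_sd
    frames += cfg.background
    np.clip(frames, 0, 255, out=frames)
    for t in cfg.targets:
        traj = _trajectory(t, cfg.n_frames)
        half = t.size / 2.0
        for k in range(cfg.n_frames):
            x0 = int(round(traj[k, 0] - half))
            y0 = int(round(traj[k, 1] - half))
            x1, y1 = x0 + int(round(t.size)), y0 + int(round(t.size))
            frames[k, max(y0, 0) : y1, max(x0, 0) : x1] = min(
                cfg.background + t.contrast, 255
            )
    clip = Clip(clip_id=cfg.clip_id, frames=frames.astype(np.uint8), fps=cfg.fps)
    return clip, target_trajectory(cfg)


@dataclass(frozen=True)
class ObserverModel:
    """One synthetic observer.

    ``tracking_weight`` (w_t) is the fraction of gaze pulled toward the
    target; the complement is pulled toward the frame centre plus central
    jitter of ``central_bias_sd`` pixels per axis. ``lag`` delays tracking by
    whole presented frames. Presentation-order disruption multiplies w_t by
    the condition's penalty (delta), so lower delta means stronger
    disruption of tracking.
    """

    tracking_weight: float = 0.7
    lag: int = 3
    gaze_noise_sd: float = 10.0
    central_bias_sd: float = 40.0
    delta_rev: float = 0.55
    delta_img: float = 0.80
    delta_rand: float = 0.60

    def __post_init__(self) -> None:
        if not 0.0 <= self.tracking_weight <= 1.0:
            raise ConfigurationError(f"tracking_weight must be in [0,1], got {self.tracking_weight}")
        for name in ("delta_rev", "delta_img", "delta_rand"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if self.lag < 0:
            raise ConfigurationError(f"lag must be >= 0, got {self.lag}")

    def penalty(self, condition: PresentationCondition) -> float:
        return {
            PresentationCondition.NORMAL_VIDEO: 1.0,
            PresentationCondition.REVERSED_VIDEO: self.delta_rev,
            PresentationCondition.NORMAL_IMAGES: self.delta_img,
            PresentationCondition.RANDOMISED_IMAGES: self.delta_rand,
        }[condition]


def generate_gaze(
    trajectory: np.ndarray,
    seq_map: SequenceMap,
    obs: ObserverModel,
    rng_seed: int | None = None,
    *,
    frame_w: int = DEFAULT_FRAME_W,
    frame_h: int = DEFAULT_FRAME_H,
    source_id: str = "observer",
    clip_id: str = "clip",
) -> GazeTrack:
    """Simulate one observer viewing one presented sequence.

    Per presented frame k (1-based), with T(k) the ground-truth target
    position at source frame ``map(clamp(k - lag))`` and w' = w_t * delta of
    the condition:

        gaze(k) = w' * T(k) + (1 - w') * (centre + jitter) + noise,

    jitter ~ N(0, central_bias_sd^2 I) and noise ~ N(0, gaze_noise_sd^2 I)
    drawn independently per frame; points are clipped to the frame extent.
    """
    trajectory = np.asarray(trajectory, dtype=float)
    n = seq_map.n_frames
    if trajectory.shape[0] < seq_map.mapping.max():
        raise InputError("trajectory shorter than the sequence map's source range")
    rng = np.random.default_rng(rng_seed)
    lagged = np.clip(np.arange(1, n + 1) - obs.lag, 1, n)
    src = seq_map.mapping[lagged - 1]  # content-aligned, lagged source frames
    target = trajectory[src - 1]
    w = obs.tracking_weight * obs.penalty(seq_map.condition)
    centre = np.array([frame_w / 2.0, frame_h / 2.0])
    jitter = rng.normal(0.0, obs.central_bias_sd, (n, 2))
    noise = rng.normal(0.0, obs.gaze_noise_sd, (n, 2))
    xy = w * target + (1.0 - w) * (centre + jitter) + noise
    xy[:, 0] = np.clip(xy[:, 0], 0.0, frame_w - 1e-6)
    xy[:, 1] = np.clip(xy[:, 1], 0.0, frame_h - 1e-6)
    return GazeTrack(
        source_id=source_id,
        clip_id=clip_id,
        condition=seq_map.condition,
        xy=xy,
        frame_w=frame_w,
        frame_h=frame_h,
    )


@dataclass
class CohortConfig:
    """Distributions of observer parameters for a synthetic cohort.

    Each (mean, sd) pair parameterises a normal draw per observer, clipped to
    the parameter's valid range; ``lag`` is rounded to whole frames. Defaults
    emulate the emulated study's cohort size of 35 observers.
    """

    n_observers: int = 35
    tracking_weight: tuple[float, float] = (0.7, 0.08)
    lag: tuple[float, float] = (3.0, 1.0)
    gaze_noise_sd: tuple[float, float] = (10.0, 2.0)
    central_bias_sd: tuple[float, float] = (40.0, 5.0)
    delta_rev: tuple[float, float] = (0.55, 0.05)
    delta_img: tuple[float, float] = (0.80, 0.05)
    delta_rand: tuple[float, float] = (0.60, 0.05)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_observers < 2:
            raise ConfigurationError(f"n_observers must be >= 2, got {self.n_observers}")

    def draw_observer(self, rng: np.random.Generator) -> ObserverModel:
        def tn(pair, lo, hi):
            return float(np.clip(rng.normal(*pair), lo, hi))

        return ObserverModel(
            tracking_weight=tn(self.tracking_weight, 0.0, 1.0),
            lag=int(round(max(rng.normal(*self.lag), 0.0))),
            gaze_noise_sd=tn(self.gaze_noise_sd, 0.5, np.inf),
            central_bias_sd=tn(self.central_bias_sd, 0.5, np.inf),
            delta_rev=tn(self.delta_rev, 0.0, 1.0),
            delta_img=tn(self.delta_img, 0.0, 1.0),
            delta_rand=tn(self.delta_rand, 0.0, 1.0),
        )


@dataclass
class CohortDataset:
    """The full factorial synthetic dataset: observers x clips x conditions."""

    scenes: list[SceneConfig]
    trajectories: dict  # clip_id -> (n_frames, 2)
    seq_maps: dict  # (clip_id, condition) -> SequenceMap
    observers: dict  # observer_id -> ObserverModel
    tracks: dict  # (observer_id, clip_id, condition) -> GazeTrack
    clip_seeds: dict  # clip_id -> render seed
    frame_w: int
    frame_h: int
    fps: float
    master_seed: int

    @property
    def observer_ids(self) -> list[str]:
        return list(self.observers)

    @property
    def clip_ids(self) -> list[str]:
        return [s.clip_id for s in self.scenes]

    def tracks_for(self, clip_id: str, condition: PresentationCondition) -> list[GazeTrack]:
        """All observers' tracks for one presented sequence, in cohort order."""
        return [self.tracks[(o, clip_id, condition)] for o in self.observers]

    def render_clip(self, clip_id: str) -> tuple[Clip, np.ndarray]:
        """(Re-)render one source clip deterministically from its stored seed."""
        scene = next(s for s in self.scenes if s.clip_id == clip_id)
        return generate_clip(scene, self.clip_seeds[clip_id])

    def to_gaze_csv(self, path, geom: ScreenGeometry | None = None) -> None:
        """Emit every track in the raw gaze CSV schema (one sample per frame
        at the frame's window midpoint, screen coordinates)."""
        from .gaze_data import write_gaze_csv

        geom = geom or ScreenGeometry.centered(1024, 768, self.frame_w, self.frame_h)
        records = []
        for (obs_id, clip_id, cond), tr in self.tracks.items():
            miss = tr.missing
            for k in range(tr.n_frames):
                if miss[k]:
                    continue
                sx, sy = frame_to_screen((tr.xy[k, 0], tr.xy[k, 1]), geom)
                records.append(
                    RawGazeRecord(
                        observer_id=obs_id,
                        clip_id=clip_id,
                        condition=cond,
                        t=(k + 0.5) / self.fps,
                        x_screen=sx,
                        y_screen=sy,
                        valid=True,
                    )
                )
        write_gaze_csv(records, path)


def random_scene(
    clip_id: str,
    rng: np.random.Generator,
    *,
    frame_w: int = DEFAULT_FRAME_W,
    frame_h: int = DEFAULT_FRAME_H,
    n_frames: int = DEFAULT_N_FRAMES,
    fps: float = DEFAULT_FPS,
) -> SceneConfig:
    """A scene with one target sweeping the frame at constant velocity.

    Speed is drawn in [2, 4] px/frame with a random heading; the start point
    is drawn uniformly from positions keeping the whole sweep inside the
    frame, so trajectories cover the frame widely rather than hugging the
    centre.
    """
    size = 24.0
    half = size / 2.0
    for _ in range(100):
        speed = rng.uniform(2.0, 4.0)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        v = np.array([np.cos(theta), np.sin(theta)]) * speed
        span = (n_frames - 1) * v
        upper = np.array([frame_w - half, frame_h - half])
        lo = np.maximum(half, half - span)
        hi = np.minimum(upper, upper - span)
        if (lo < hi).all():
            start = rng.uniform(lo, hi)
            return SceneConfig(
                clip_id=clip_id,
                targets=[TargetSpec(start=tuple(start), velocity=tuple(v), size=size)],
                frame_w=frame_w,
                frame_h=frame_h,
                n_frames=n_frames,
                fps=fps,
            )
    raise ConfigurationError("could not place a target sweep inside the frame")


def default_scenes(n_clips: int, seed: int = 0, **kwargs) -> list[SceneConfig]:
    """Deterministic list of varied single-target scenes."""
    rng = np.random.default_rng(seed)
    return [random_scene(f"clip{c + 1:02d}", rng, **kwargs) for c in range(n_clips)]


def generate_cohort(
    cohort: CohortConfig, scenes: Sequence[SceneConfig]
) -> CohortDataset:
    """Generate the full factorial dataset: every observer views every clip
    in all four conditions.

    All randomness flows from ``cohort.master_seed`` through a spawned seed
    tree, so the same configuration always yields byte-identical output.
    """
    scenes = list(scenes)
    if not scenes:
        raise ConfigurationError("need at least one scene")
    frame_w, frame_h, fps = scenes[0].frame_w, scenes[0].frame_h, scenes[0].fps

    root = np.random.SeedSequence(cohort.master_seed)
    ss_obs, ss_seq, ss_clip, ss_track = root.spawn(4)

    obs_rng = np.random.default_rng(ss_obs)
    observers = {
        f"obs{i + 1:02d}": cohort.draw_observer(obs_rng)
        for i in range(cohort.n_observers)
    }

    seq_rng = np.random.default_rng(ss_seq)
    clip_seed_rng = np.random.default_rng(ss_clip)
    trajectories: dict = {}
    seq_maps: dict = {}
    clip_seeds: dict = {}
    for scene in scenes:
        trajectories[scene.clip_id] = target_trajectory(scene)
        clip_seeds[scene.clip_id] = int(clip_seed_rng.integers(2**31 - 1))
        # sequence maps do not need rendered frames; build them from a frame
        # index stub so randomised still order is drawn per clip
        stub = Clip(
            clip_id=scene.clip_id,
            frames=np.zeros((scene.n_frames, 1, 1), dtype=np.uint8),
            fps=scene.fps,
        )
        rand_seed = int(seq_rng.integers(2**31 - 1))
        for cond, (_, smap) in generate_all_sequences(stub, rng_seed=rand_seed).items():
            seq_maps[(scene.clip_id, cond)] = smap

    track_seeds = np.random.default_rng(ss_track)
    tracks: dict = {}
    for obs_id, model in observers.items():
        for scene in scenes:
            for cond in CONDITIONS:
                seed = int(track_seeds.integers(2**31 - 1))
                tracks[(obs_id, scene.clip_id, cond)] = generate_gaze(
                    trajectories[scene.clip_id],
                    seq_maps[(scene.clip_id, cond)],
                    model,
                    seed,
                    frame_w=frame_w,
                    frame_h=frame_h,
                    source_id=obs_id,
                    clip_id=scene.clip_id,
                )
    return CohortDataset(
        scenes=scenes,
        trajectories=trajectories,
        seq_maps=seq_maps,
        observers=observers,
        tracks=tracks,
        clip_seeds=clip_seeds,
        frame_w=frame_w,
        frame_h=frame_h,
        fps=fps,
        master_seed=cohort.master_seed,
    )


def emit_raw_samples(
    track: GazeTrack,
    geom: ScreenGeometry,
    fps: float = DEFAULT_FPS,
    sample_rate: float = 50.0,
    rng_seed: int | None = None,
    position_jitter_sd: float = 0.0,
    blink_frames: Sequence[int] = (),
) -> list[RawGazeRecord]:
    """Expand a frame-rate gaze track into raw tracker samples.

    Samples are emitted at ``sample_rate`` Hz over the presented duration;
    each takes the gaze point of the frame whose window contains it (plus
    optional isotropic position jitter) in screen coordinates. Samples whose
    frame is listed in ``blink_frames`` (1-based) or is MISSING are emitted
    with ``valid=False``.
    """
    rng = np.random.default_rng(rng_seed)
    n_samples = int(np.floor(track.n_frames / fps * sample_rate))
    blink = set(int(b) for b in blink_frames)
    miss = track.missing
    records = []
    for j in range(n_samples):
        t = j / sample_rate
        k = int(np.floor(t * fps))  # 0-based frame
        k = min(k, track.n_frames - 1)
        if (k + 1) in blink or miss[k]:
            records.append(
                RawGazeRecord(
                    observer_id=track.source_id,
                    clip_id=track.clip_id,
                    condition=track.condition,
                    t=t,
                    x_screen=float(geom.offset_x),
                    y_screen=float(geom.offset_y),
                    valid=False,
                )
            )
            continue
        p = track.xy[k] + rng.normal(0.0, position_jitter_sd, 2)
        p[0] = np.clip(p[0], 0.0, geom.frame_w - 1e-6)
        p[1] = np.clip(p[1], 0.0, geom.frame_h - 1e-6)
        sx, sy = frame_to_screen((p[0], p[1]), geom)
        records.append(
            RawGazeRecord(
                observer_id=track.source_id,
                clip_id=track.clip_id,
                condition=track.condition,
                t=t,
                x_screen=sx,
                y_screen=sy,
                valid=True,
            )
        )
    return records


def estimate_central_bias_sd(
    tracks: Sequence[GazeTrack],
    frame_w: int | None = None,
    frame_h: int | None = None,
    gaze_noise_sd: float = 0.0,
) -> float:
    """Recover the central-bias spread from mean centre distances.

    Assumes the tracks come from the generator's pure central-gaze regime
    (tracking weight 0), where gaze is isotropic Gaussian about the frame
    centre: the radial distance is then Rayleigh with mean
    sigma * sqrt(pi/2), sigma^2 = central_bias_sd^2 + gaze_noise_sd^2.
    Inverts that identity on the pooled mean distance, subtracting a known
    gaze-noise contribution in quadrature.
    """
    from .similarity import central_bias

    dists = []
    for tr in tracks:
        cb = central_bias(tr, frame_w, frame_h)
        if cb.scorable:
            dists.append(cb.mean_dist)
    if not dists:
        raise InputError("no scorable tracks for central-bias recovery")
    sigma_tot = float(np.mean(dists)) / np.sqrt(np.pi / 2.0)
    return float(np.sqrt(max(sigma_tot**2 - gaze_noise_sd**2, 0.0)))
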