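"""End-to-end orchestration: cohort + predictors in, report tables out.

The report mirrors the three analyses the similarity module supports:

* a per-source, per-condition, per-clip **similarity table** (human
  leave-one-out rows plus one row per predictor), the per-condition
  benchmark being built from that condition's own human gaze;
* a **cross-sequence table** comparing each source's gaze (or predictions)
  on identical content between the normal sequence and the reversed /
  normal-image sequences, normalised by the normal-condition benchmark;
* a **central-bias table** of mean gaze distance from the frame centre;

plus human and chance baseline rows and run metadata (seeds, counts,
exclusions). Exclusions — unscorable clips, mismatched tracks — are never
fatal mid-run: they are recorded with reasons and the run continues.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import GazebenchError, InputError
from .gaze_data import CONDITIONS, GazeTrack, PresentationCondition
from .predictors import center_predictor, motion_energy_predictor, random_predictor
from .sequencing import Clip, SequenceMap, make_sequence
from .similarity import (
    BenchmarkTrack,
    build_benchmark,
    central_bias,
    chance_baseline,
    clip_similarity,
    cross_sequence_similarity,
    interobserver_similarity,
)
from .simulate import CohortDataset

__all__ = [
    "EvaluationConfig",
    "ReportBundle",
    "evaluate_cohort",
    "run_evaluation",
    "summarize",
    "HUMAN_BASELINE_ID",
    "CHANCE_BASELINE_ID",
]

HUMAN_BASELINE_ID = "human_baseline"
CHANCE_BASELINE_ID = "chance_baseline"

#: Cross-sequence comparisons reported (test condition -> label).
CROSS_COMPARISONS = {
    PresentationCondition.REVERSED_VIDEO: "normal_vs_reversed",
    PresentationCondition.NORMAL_IMAGES: "normal_vs_images",
}

_BUILTIN_PREDICTORS: dict[str, Callable[..., GazeTrack]] = {
    "motion_energy": lambda clip, seed: motion_energy_predictor(clip),
    "center": lambda clip, seed: center_predictor(clip),
    "random": lambda clip, seed: random_predictor(clip, rng_seed=seed),
}


@dataclass
class EvaluationConfig:
    """File-based configuration for :func:`run_evaluation`."""

    gaze_csv: str | Path
    clip_dirs: list[str | Path]
    out_dir: str | Path
    frame_w: int
    frame_h: int
    predictors: list[str] = field(default_factory=lambda: ["motion_energy", "center", "random"])
    predictor_track_csvs: list[str | Path] = field(default_factory=list)
    conditions: list[PresentationCondition] = field(default_factory=lambda: list(CONDITIONS))
    chance_reps: int = 100
    chance_seed: int = 0
    predictor_seed: int = 1
    aggregation: str = "clips_then_observers"

    @classmethod
    def from_yaml(cls, path) -> "EvaluationConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if "conditions" in raw:
            raw["conditions"] = [PresentationCondition(c) for c in raw["conditions"]]
        return cls(**raw)


@dataclass
class ReportBundle:
    """All tables produced by one evaluation run."""

    similarity: pd.DataFrame
    cross_sequence: pd.DataFrame
    central_bias: pd.DataFrame
    baselines: pd.DataFrame
    metadata: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.similarity.to_csv(out / "similarity.csv", index=False)
        self.cross_sequence.to_csv(out / "cross_sequence.csv", index=False)
        self.central_bias.to_csv(out / "central_bias.csv", index=False)
        self.baselines.to_csv(out / "baselines.csv", index=False)
        lines = [f"{k}: {v}" for k, v in self.metadata.items() if k != "exclusions"]
        for exc in self.metadata.get("exclusions", []):
            lines.append(f"excluded: {exc}")
        (out / "run_log.txt").write_text("\n".join(lines) + "\n")


def _sd(vals: Sequence[float]) -> float:
    vals = [v for v in vals if v is not None and not np.isnan(v)]
    return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0


def _frame_sd(cs) -> float:
    svals = [f.s for f in cs.frames if f.status == "OK"]
    return _sd(svals)


def evaluate_cohort(
    dataset: CohortDataset,
    predictor_names: Sequence[str] = ("motion_energy", "center", "random"),
    external_tracks: dict | None = None,
    chance_reps: int = 100,
    seed: int = 0,
    conditions: Sequence[PresentationCondition] = CONDITIONS,
) -> ReportBundle:
    """Run the full analysis on an in-memory synthetic cohort.

    ``external_tracks`` maps ``(source_id, clip_id, condition)`` to
    pre-computed prediction tracks (the adapter path for third-party saliency
    models); built-in predictors are recomputed from the rendered presented
    clips. ``seed`` drives the chance baseline and any stochastic predictor.
    """
    t0 = time.monotonic()
    exclusions: list[str] = []
    sim_rows, cross_rows, bias_rows, base_rows = [], [], [], []

    root = np.random.SeedSequence(seed)
    chance_rng = np.random.default_rng(root.spawn(1)[0])
    pred_seed_rng = np.random.default_rng(root.spawn(1)[0])

    # --- benchmarks (per clip x condition, from that condition's human gaze)
    benchmarks: dict[tuple[str, PresentationCondition], BenchmarkTrack] = {}
    for clip_id in dataset.clip_ids:
        for cond in conditions:
            benchmarks[(clip_id, cond)] = build_benchmark(
                dataset.tracks_for(clip_id, cond)
            )

    # --- human baseline: all-except-one protocol, per clip x condition
    loo_scores: dict[tuple[str, PresentationCondition], list] = {}
    for clip_id in dataset.clip_ids:
        for cond in conditions:
            scores = interobserver_similarity(dataset.tracks_for(clip_id, cond))
            loo_scores[(clip_id, cond)] = scores
            for cs in scores:
                if not cs.scorable:
                    exclusions.append(
                        f"{cs.source_id}/{clip_id}/{cond.value}: unscorable leave-one-out clip"
                    )
                    continue
                sim_rows.append(
                    (cs.source_id, cond.value, clip_id, cs.mean_s, _frame_sd(cs),
                     cs.n_scored, cs.n_skipped)
                )

    # --- chance baseline, per clip x condition
    chance_by_cond: dict[PresentationCondition, list[float]] = {c: [] for c in conditions}
    for clip_id in dataset.clip_ids:
        for cond in conditions:
            cb = chance_baseline(
                benchmarks[(clip_id, cond)],
                n_reps=chance_reps,
                rng_seed=int(chance_rng.integers(2**31 - 1)),
            )
            chance_by_cond[cond].append(cb.mean_s)
            sim_rows.append(
                (CHANCE_BASELINE_ID, cond.value, clip_id, cb.mean_s, cb.sd_s,
                 benchmarks[(clip_id, cond)].n_frames, 0)
            )

    # --- predictors on the presented clips
    pred_tracks: dict[tuple[str, str, PresentationCondition], GazeTrack] = {}
    for clip_id in dataset.clip_ids:
        source_clip, _ = dataset.render_clip(clip_id)
        for cond in conditions:
            smap = dataset.seq_maps[(clip_id, cond)]
            presented = Clip(
                clip_id=clip_id, frames=source_clip.frames[smap.mapping - 1],
                fps=source_clip.fps,
            )
            for name in predictor_names:
                try:
                    tr = _BUILTIN_PREDICTORS[name](
                        presented, int(pred_seed_rng.integers(2**31 - 1))
                    )
                except KeyError:
                    raise InputError(f"unknown predictor {name!r}") from None
                except GazebenchError as exc:
                    exclusions.append(f"{name}/{clip_id}/{cond.value}: {exc}")
                    continue
                tr.condition = cond
                pred_tracks[(name, clip_id, cond)] = tr
    if external_tracks:
        pred_tracks.update(external_tracks)

    pred_ids = sorted({k[0] for k in pred_tracks})
    for (name, clip_id, cond), tr in pred_tracks.items():
        bench = benchmarks.get((clip_id, cond))
        if bench is None:
            continue
        try:
            cs = clip_similarity(bench, tr)
        except GazebenchError as exc:
            exclusions.append(f"{name}/{clip_id}/{cond.value}: {exc}")
            continue
        if not cs.scorable:
            exclusions.append(f"{name}/{clip_id}/{cond.value}: unscorable clip")
            continue
        sim_rows.append(
            (name, cond.value, clip_id, cs.mean_s, _frame_sd(cs), cs.n_scored, cs.n_skipped)
        )

    # --- cross-sequence similarity (humans and predictors), content-aligned,
    #     normalised by the normal-condition benchmark
    for clip_id in dataset.clip_ids:
        bench_ref = benchmarks.get((clip_id, PresentationCondition.NORMAL_VIDEO))
        if bench_ref is None:
            continue
        for cond, label in CROSS_COMPARISONS.items():
            if cond not in conditions:
                continue
            smap = dataset.seq_maps[(clip_id, cond)]
            for obs_id in dataset.observer_ids:
                cs = cross_sequence_similarity(
                    dataset.tracks[(obs_id, clip_id, PresentationCondition.NORMAL_VIDEO)],
                    dataset.tracks[(obs_id, clip_id, cond)],
                    smap,
                    bench_ref,
                )
                if cs.scorable:
                    cross_rows.append((obs_id, label, clip_id, cs.mean_s))
            for name in pred_ids:
                ref = pred_tracks.get((name, clip_id, PresentationCondition.NORMAL_VIDEO))
                test = pred_tracks.get((name, clip_id, cond))
                if ref is None or test is None:
                    continue
                cs = cross_sequence_similarity(ref, test, smap, bench_ref)
                if cs.scorable:
                    cross_rows.append((name, label, clip_id, cs.mean_s))
                else:
                    exclusions.append(
                        f"{name}/{clip_id}/{label}: unscorable cross-sequence clip"
                    )

    # --- central fixation bias (humans and predictors)
    for clip_id in dataset.clip_ids:
        for cond in conditions:
            for tr in dataset.tracks_for(clip_id, cond):
                cb = central_bias(tr)
                if cb.scorable:
                    bias_rows.append((tr.source_id, cond.value, clip_id, cb.mean_dist))
            for name in pred_ids:
                tr = pred_tracks.get((name, clip_id, cond))
                if tr is None:
                    continue
                cb = central_bias(tr)
                if cb.scorable:
                    bias_rows.append((name, cond.value, clip_id, cb.mean_dist))

    # --- baseline summary rows (human LOO and chance, per condition)
    for cond in conditions:
        per_obs = []
        for obs_idx, obs_id in enumerate(dataset.observer_ids):
            vals = [
                loo_scores[(c, cond)][obs_idx].mean_s
                for c in dataset.clip_ids
                if loo_scores[(c, cond)][obs_idx].scorable
            ]
            if vals:
                per_obs.append(float(np.mean(vals)))
        base_rows.append(
            (HUMAN_BASELINE_ID, cond.value, float(np.mean(per_obs)), _sd(per_obs),
             len(per_obs))
        )
        base_rows.append(
            (CHANCE_BASELINE_ID, cond.value, float(np.mean(chance_by_cond[cond])),
             _sd(chance_by_cond[cond]), len(chance_by_cond[cond]))
        )

    similarity = pd.DataFrame(
        sim_rows,
        columns=["source_id", "condition", "clip_id", "mean_S", "sd_S", "n_scored", "n_skipped"],
    )
    cross = pd.DataFrame(
        cross_rows, columns=["source_id", "comparison", "clip_id", "mean_S"]
    )
    bias = pd.DataFrame(
        bias_rows, columns=["source_id", "condition", "clip_id", "mean_center_dist_px"]
    )
    baselines = pd.DataFrame(
        base_rows, columns=["source_id", "condition", "mean_S", "sd_S", "n"]
    )
    metadata = {
        "seed": seed,
        "chance_reps": chance_reps,
        "n_observers": len(dataset.observer_ids),
        "n_clips": len(dataset.clip_ids),
        "n_conditions": len(list(conditions)),
        "n_presented_sequences": len(dataset.clip_ids) * len(list(conditions)),
        "predictors": list(pred_ids),
        "elapsed_s": round(time.monotonic() - t0, 2),
        "exclusions": exclusions,
    }
    return ReportBundle(similarity, cross, bias, baselines, metadata)


def summarize(
    report: ReportBundle, level: str = "condition", aggregation: str = "clips_then_observers"
) -> pd.DataFrame:
    """Aggregate the similarity table to clip, condition or overall level.

    ``clips_then_observers`` (default) averages each source's clip scores
    first, then reports mean and sd across sources of the same kind;
    ``pooled`` treats every (source, clip) score as one sample. Human
    observer rows are pooled under their own ids; baselines and predictors
    keep theirs.
    """
    df = report.similarity
    if level == "clip":
        return df.copy()
    if level == "condition":
        keys = ["source_id", "condition"]
    elif level == "overall":
        keys = ["source_id"]
    else:
        raise InputError(f"unknown aggregation level {level!r}")
    if aggregation == "clips_then_observers":
        per = df.groupby(keys, sort=False)["mean_S"]
        out = per.agg(mean_S="mean", sd_S="std", n="count").reset_index()
        out["sd_S"] = out["sd_S"].fillna(0.0)
        return out
    if aggregation == "pooled":
        g = df.groupby(keys, sort=False)["mean_S"]
        return g.agg(mean_S="mean", sd_S="std", n="count").reset_index()
    raise InputError(f"unknown aggregation ordering {aggregation!r}")


def run_evaluation(cfg: EvaluationConfig) -> ReportBundle:
    """File-based entry point: read gaze and clips from disk, evaluate,
    write the report tables and a run log to ``cfg.out_dir``."""
    from .gaze_data import read_track_csv
    from .sequencing import read_clip_dir
    from .simulate import CohortDataset, SceneConfig, TargetSpec

    tracks_list = read_track_csv(cfg.gaze_csv, cfg.frame_w, cfg.frame_h)
    if not tracks_list:
        raise InputError(f"{cfg.gaze_csv}: no gaze tracks found")

    clips = {c.clip_id: c for c in (read_clip_dir(d) for d in cfg.clip_dirs)}
    # rebuild sequence maps: normal/reversed are structural; image-sequence
    # maps must be provided alongside clips as sequence_map.csv when scored
    seq_maps = {}
    for clip_id, clip in clips.items():
        for cond in cfg.conditions:
            if cond == PresentationCondition.NORMAL_VIDEO:
                seq_maps[(clip_id, cond)] = SequenceMap.identity(clip.n_frames)
            elif cond == PresentationCondition.REVERSED_VIDEO:
                seq_maps[(clip_id, cond)] = SequenceMap.reverse(clip.n_frames)
            else:
                _, smap = make_sequence(clip, cond, rng_seed=cfg.predictor_seed)
                seq_maps[(clip_id, cond)] = smap

    observers = sorted({t.source_id for t in tracks_list})
    tracks = {(t.source_id, t.clip_id, t.condition): t for t in tracks_list}

    external = {}
    for path in cfg.predictor_track_csvs:
        for t in read_track_csv(path, cfg.frame_w, cfg.frame_h):
            external[(t.source_id, t.clip_id, t.condition)] = t

    any_clip = next(iter(clips.values()))
    dataset = CohortDataset(
        scenes=[
            SceneConfig(
                clip_id=c.clip_id,
                targets=[TargetSpec(start=(c.frame_w / 2, c.frame_h / 2), velocity=(0, 0))],
                frame_w=c.frame_w,
                frame_h=c.frame_h,
                n_frames=c.n_frames,
                fps=c.fps,
            )
            for c in clips.values()
        ],
        trajectories={},
        seq_maps=seq_maps,
        observers={o: None for o in observers},
        tracks=tracks,
        clip_seeds={},
        frame_w=cfg.frame_w,
        frame_h=cfg.frame_h,
        fps=any_clip.fps,
        master_seed=cfg.chance_seed,
    )
    # file-based datasets render nothing: patch clip access to stored frames
    dataset.render_clip = lambda clip_id: (clips[clip_id], None)  # type: ignore[method-assign]

    report = evaluate_cohort(
        dataset,
        predictor_names=cfg.predictors,
        external_tracks=external,
        chance_reps=cfg.chance_reps,
        seed=cfg.chance_seed,
        conditions=cfg.conditions,
    )
    report.write(cfg.out_dir)
    return report
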