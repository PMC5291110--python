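"""Reproduction entry point for the original deposited gaze data.

The study's coded gaze data (its "Data S1" supplement) is not distributed
with this package. To rerun the headline numbers on it, export the per-frame
gaze locations to the frame-track CSV schema
(``source_id,clip_id,condition,frame,x,y,missing``; one row per observer,
clip, condition and presented frame, coordinates in 720x404 frame pixels)
and point :func:`reproduce_study_baselines` at the file. The routine
recomputes, per presentation condition, the all-except-one human baseline
and the 100-repetition uniform-random chance baseline.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path

import numpy as np

from .errors import InputError
from .gaze_data import read_track_csv
from .similarity import chance_baseline, interobserver_similarity

__all__ = ["STUDY_DATA_PATH", "reproduce_study_baselines"]

#: Where the converted deposited gaze export is expected.
STUDY_DATA_PATH = Path("data/study_gaze.csv")

STUDY_FRAME_W = 720
STUDY_FRAME_H = 404


def reproduce_study_baselines(
    gaze_csv=STUDY_DATA_PATH,
    chance_reps: int = 100,
    seed: int = 0,
) -> dict:
    """Human and chance baselines from a deposited per-frame gaze export.

    Returns a dict with ``human_baseline`` (mean leave-one-out similarity
    over observers, clips and conditions), ``human_baseline_by_condition``,
    ``chance_by_condition`` and ``chance_range`` (min, max over conditions).
    """
    gaze_csv = Path(gaze_csv)
    if not gaze_csv.exists():
        raise FileNotFoundError(
            f"{gaze_csv}: deposited study gaze export not found; see "
            "gazebench.study module docstring for the expected schema"
        )
    tracks = read_track_csv(gaze_csv, STUDY_FRAME_W, STUDY_FRAME_H)
    by_seq = defaultdict(list)
    for tr in tracks:
        by_seq[(tr.clip_id, tr.condition)].append(tr)

    rng = np.random.default_rng(seed)
    human_by_cond = defaultdict(list)
    chance_by_cond = defaultdict(list)
    for (clip_id, cond), seq_tracks in by_seq.items():
        if len(seq_tracks) < 2:
            raise InputError(
                f"{clip_id}/{cond.value}: need >= 2 observers, got {len(seq_tracks)}"
            )
        for cs in interobserver_similarity(seq_tracks):
            if cs.scorable:
                human_by_cond[cond.value].append(cs.mean_s)
        from .similarity import build_benchmark

        cb = chance_baseline(
            build_benchmark(seq_tracks),
            n_reps=chance_reps,
            rng_seed=int(rng.integers(2**31 - 1)),
        )
        chance_by_cond[cond.value].append(cb.mean_s)

    human_by_cond = {c: float(np.mean(v)) for c, v in human_by_cond.items()}
    chance_by_cond = {c: float(np.mean(v)) for c, v in chance_by_cond.items()}
    return {
        "human_baseline": float(np.mean(list(human_by_cond.values()))),
        "human_baseline_by_condition": human_by_cond,
        "chance_by_condition": chance_by_cond,
        "chance_range": (
            min(chance_by_cond.values()),
            max(chance_by_cond.values()),
        ),
    }
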