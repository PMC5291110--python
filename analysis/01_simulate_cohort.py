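#!/usr/bin/env python
"""Generate the synthetic viewing study: moving-target clips, the four
presentation sequences per clip, and a 35-observer gaze cohort.

Writes the raw gaze log (gaze CSV schema), ground-truth trajectories and
the presented->source frame maps under results/data/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from config import DATA_DIR, N_CLIPS, N_OBSERVERS, build_dataset

from gazebench import condition_count


def main() -> None:
    out = Path(DATA_DIR)
    out.mkdir(parents=True, exist_ok=True)
    ds = build_dataset()

    ds.to_gaze_csv(out / "gaze.csv")
    rows = [
        (clip_id, k + 1, x, y)
        for clip_id, traj in ds.trajectories.items()
        for k, (x, y) in enumerate(traj)
    ]
    pd.DataFrame(rows, columns=["clip_id", "frame", "x", "y"]).to_csv(
        out / "trajectories.csv", index=False
    )
    for (clip_id, cond), smap in ds.seq_maps.items():
        smap.to_csv(out / f"seqmap_{clip_id}_{cond.value}.csv")

    n_seq = condition_count(N_CLIPS)
    print(
        f"Simulated {N_OBSERVERS} observers viewing {N_CLIPS} clips in 4 "
        f"presentation conditions: {n_seq} presented sequences, "
        f"{len(ds.tracks)} gaze tracks of {ds.tracks[next(iter(ds.tracks))].n_frames} "
        f"frames each -> {out}/"
    )


if __name__ == "__main__":
    main()
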