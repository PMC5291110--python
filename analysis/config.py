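"""Shared settings for the analysis scripts.

One seed drives scene layout, cohort parameters and every stochastic stage,
so rerunning any script reproduces the same tables. Six clips keep the full
factorial (observers x clips x 4 conditions) quick to evaluate on one CPU
while leaving every aggregate well-determined; the cohort size matches the
emulated protocol (35 observers).
"""

SEED = 20260920
N_CLIPS = 6
N_OBSERVERS = 35
CHANCE_REPS = 100

DATA_DIR = "results/data"
TABLE_DIR = "results/tables"


def build_dataset():
    from gazebench import CohortConfig, default_scenes, generate_cohort

    scenes = default_scenes(N_CLIPS, seed=SEED)
    return generate_cohort(
        CohortConfig(n_observers=N_OBSERVERS, master_seed=SEED), scenes
    )
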