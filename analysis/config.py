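"""Shared run configuration for the numbered analysis scripts.

One desk-scale parameterization of the full study: a two-cluster landscape
(60 x 60 km regions separated by a 40-km data gap), 200 + 80 presences,
2 x 200 pseudoabsence replicates, and a fast GBM setting whose
learning-rate x tree-count product matches the reference configuration.
Every script derives its randomness from the single SEED below.
"""

from pathlib import Path

import numpy as np

from hsmtransfer.evaluation import ExperimentConfig
from hsmtransfer.pipeline import RunConfig
from hsmtransfer.synthio import LandscapeConfig, ScenarioConfig

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"
RUN_DIR = RESULTS / "run"


def build_config(seed: int = SEED) -> RunConfig:
    ss = np.random.SeedSequence(seed)
    s_land, s_scen, s_exp, s_run = (
        int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(4))
    landscape = LandscapeConfig(
        region_a=(0.0, 0.0, 60_000.0, 60_000.0),
        region_b=(100_000.0, 0.0, 160_000.0, 60_000.0),
        cell_size=1_000.0, spatial_corr_range=5_000.0, seed=s_land)
    scenario = ScenarioConfig(landscape=landscape, n_occ_a=200, n_occ_b=80,
                              seed=s_scen)
    experiment = ExperimentConfig(
        pa_n=200, pa_sets=2,
        gbm_learning_rate=0.05, gbm_max_trees=100, gbm_tree_grid_step=50,
        gbm_cv_folds=3, seed=s_exp)
    return RunConfig(scenario=scenario, experiment=experiment,
                     study_sample_size=3_000, overlap_R=60, overlap_reps=199,
                     overlap_background_n=1_000, seed=s_run)
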