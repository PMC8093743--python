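"""Shared fixtures: a small but fully featured synthetic scenario.

The small scenario keeps both regions at 40 x 40 km so landscape generation,
dataset assembly, and model fits all run in seconds while preserving every
structural property the tests assert (two disjunct clusters, 31 candidate
layers, collinear variable families, seasonal monthly stacks).
"""

import numpy as np
import pandas as pd
import pytest

from hsmtransfer import predictors, sampling, synthio

SMALL_LANDSCAPE = dict(
    region_a=(0.0, 0.0, 40_000.0, 40_000.0),
    region_b=(70_000.0, 0.0, 110_000.0, 40_000.0),
    cell_size=1_000.0,
    spatial_corr_range=5_000.0,
    fine_factor=5,
    seed=11,
)


@pytest.fixture(scope="session")
def small_landscape():
    return synthio.make_landscape(synthio.LandscapeConfig(**SMALL_LANDSCAPE))


@pytest.fixture(scope="session")
def small_scenario():
    cfg = synthio.ScenarioConfig(
        landscape=synthio.LandscapeConfig(**SMALL_LANDSCAPE),
        n_occ_a=150, n_occ_b=60, seed=3)
    return synthio.make_disjunct_scenario(cfg)


@pytest.fixture(scope="session")
def candidate_stack(small_scenario):
    return predictors.build_candidate_stack(small_scenario.landscape)


@pytest.fixture(scope="session")
def small_datasets(small_scenario, candidate_stack):
    return sampling.assemble_datasets(
        small_scenario.occ("A"), small_scenario.occ("B"), candidate_stack,
        pa_n=150, pa_sets=2, pa_outer=60_000.0, seed=5)


@pytest.fixture(scope="session")
def fitted_pair(small_datasets, candidate_stack):
    """One fitted GAM and GBM on a 4-variable subset of the first dataset."""
    from hsmtransfer import models

    ds = small_datasets[0]
    variables = ["bio01", "bio06", "Srad_MayOct_Mean", "Grasslands"]
    gam = models.fit_gam(ds.values, variables)
    gbm = models.fit_gbm(ds.values, variables, learning_rate=0.05,
                         max_trees=100, tree_grid_step=50, cv_folds=3, seed=1)
    assert gam.ok and gbm.ok
    return ds, gam, gbm


def toy_stack(n_layers=3, nr=8, nc=10, cell=100.0, seed=0, names=None):
    """Deterministic small PredictorStack with no nodata."""
    from hsmtransfer.raster import PredictorStack

    rng = np.random.default_rng(seed)
    data = rng.normal(size=(n_layers, nr, nc))
    if names is None:
        names = [f"v{i}" for i in range(n_layers)]
    return PredictorStack(names, data, (0.0, 0.0), cell,
                          np.ones((nr, nc), dtype=bool))
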