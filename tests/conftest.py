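"""Shared fixtures: a small synthetic landscape with scaled covariates.

The 20-row home-range table under ``data/`` is a synthetic stand-in
constructed to reproduce the published 20-animal summary statistics
(group means, ranges and Kruskal-Wallis statistics); it is not the
original telemetry product.
"""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from habconn import covariates as cov
from habconn import synth
from habconn.geodata import Grid

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def landscape():
    cfg = synth.LandscapeConfig(nrows=120, ncols=120, seed=42)
    return synth.generate_landcover(cfg), synth.generate_lines(cfg)


@pytest.fixture(scope="session")
def stack(landscape):
    lc, lines = landscape
    grids = {
        "forest_7km2": cov.window_proportion(lc, synth.CLASS_CODES["forest"], 7.0),
        "pasture_7km2": cov.window_proportion(lc, synth.CLASS_CODES["pasture"], 7.0),
        "dist_main_roads": cov.distance_to(lines, lc, classes=("high_traffic",)),
    }
    return cov.scale_covariates(cov.CovariateStack(grids))


@pytest.fixture(scope="session")
def truth():
    return synth.TruthModel(
        beta={"forest_7km2": 1.0, "pasture_7km2": 0.5}, intercept=-2.0
    )


@pytest.fixture(scope="session")
def homerange_table():
    return pd.read_csv(DATA / "synthetic_homeranges.csv")


@pytest.fixture
def uniform_grid():
    def make(nrows=5, ncols=5, value=1.0, cell_size=30.0, nodata=-9999.0):
        return Grid(np.full((nrows, ncols), value), cell_size, (0.0, 0.0), nodata)

    return make
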