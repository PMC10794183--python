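"""Shared fixtures: small synthetic studies reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from ejdisp.counties import CountyMosaic
from ejdisp.grids import GridField
from ejdisp.pipeline import attach_covariates, build_analysis_table
from ejdisp.synthetic import SyntheticConfig, make_counties, make_demographics


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    # 4 states on a 2x2 layout -> 480 x 400 km domain; resolution 40 divides it
    return SyntheticConfig(
        n_states=4, counties_per_state=6, grid_resolution=40.0, seed=7
    )


@pytest.fixture(scope="session")
def small_mosaic(small_config):
    return make_counties(small_config)


@pytest.fixture(scope="session")
def small_demographics(small_config, small_mosaic):
    return make_demographics(small_config, small_mosaic)


@pytest.fixture(scope="session")
def small_covariates(small_config, small_mosaic, small_demographics):
    return attach_covariates(small_demographics, small_mosaic)


@pytest.fixture(scope="session")
def fit_config() -> SyntheticConfig:
    # 8 states x 12 counties x 4 periods = 384 records per outcome series
    return SyntheticConfig(
        n_states=8,
        counties_per_state=12,
        seed=11,
        effect_spec={"pct_black": {"type": "linear", "slope": 1.5}},
    )


@pytest.fixture(scope="session")
def fit_data(fit_config):
    table, truths = build_analysis_table(
        fit_config,
        planted_effects={"chg_industry_SO2": fit_config.effect_spec},
    )
    return table, truths


def toy_mosaic(decade: int = 1970) -> CountyMosaic:
    """Two states side by side, two counties each, on [0,4] x [0,1] km."""
    rows = [
        {"county_id": "A1", "state_id": "A", "decade": decade,
         "geometry": box(0, 0, 1, 1)},
        {"county_id": "A2", "state_id": "A", "decade": decade,
         "geometry": box(1, 0, 2, 1)},
        {"county_id": "B1", "state_id": "B", "decade": decade,
         "geometry": box(2, 0, 3, 1)},
        {"county_id": "B2", "state_id": "B", "decade": decade,
         "geometry": box(3, 0, 4, 1)},
    ]
    return CountyMosaic(pd.DataFrame(rows))


def toy_grid(flux, year: int = 1970, sector: str = "industry",
             pollutant: str = "SO2") -> GridField:
    """Grid over [0,4] x [0,1] with 1x1 km cells and the given 1x4 flux row."""
    flux = np.asarray(flux, dtype=float).reshape(1, -1)
    nx = flux.shape[1]
    return GridField(
        x_edges=np.arange(nx + 1, dtype=float),
        y_edges=np.array([0.0, 1.0]),
        flux=flux,
        pollutant=pollutant,
        sector=sector,
        year=year,
    )
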