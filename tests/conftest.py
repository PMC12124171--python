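import numpy as np
import pytest

from cyclecover import (
    CleaningConfig,
    Season,
    SeasonNiche,
    SpeciesSimConfig,
    WorldConfig,
    clean_records,
    generate_world,
    prepare_seasonal_datasets,
    simulate_species,
)


@pytest.fixture(scope="session")
def small_world():
    """A 40x40 world with 3 climate layers, PAs and 5 countries."""
    cfg = WorldConfig(grid_nrows=40, grid_ncols=40, n_climate_layers=3,
                      n_countries=5, pa_area_fraction=0.2, seed=101)
    return generate_world(cfg)


@pytest.fixture(scope="session")
def medium_world():
    """A 100x100 world used for calibration-sensitive checks."""
    cfg = WorldConfig(grid_nrows=100, grid_ncols=100, n_climate_layers=3,
                      n_countries=8, pa_area_fraction=0.16, seed=202)
    return generate_world(cfg)


@pytest.fixture(scope="session")
def two_season_species(small_world):
    cfg = SpeciesSimConfig(
        name="sp_test",
        niche={Season.S1: SeasonNiche(0.0, {"bio01": 2.0}),
               Season.S3: SeasonNiche(0.3, {"bio02": -1.8})},
        records_per_season=250, contamination=0.2, seed=7)
    return simulate_species(small_world, cfg)


@pytest.fixture(scope="session")
def seasonal_sets(small_world, two_season_species):
    records, _, _ = two_season_species
    cleaned, _ = clean_records(records)
    sets, _ = prepare_seasonal_datasets(cleaned, small_world.grid, CleaningConfig())
    return sets
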