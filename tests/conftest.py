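import datetime as dt

import numpy as np
import pytest

from reedmap import make_fixture, make_phenology
from reedmap.core import TWO_SEASON_WINDOWS, MultibandPass
from reedmap.synthetic_scene import (
    DemParams,
    LandscapeSpec,
    PassSpec,
    generate_dataset,
    generate_landscape,
    simulate_pass,
)

SUMMER_DATE = dt.date(2016, 7, 15)
WINTER_DATE = dt.date(2016, 12, 15)


def constant_pass(value: float, shape=(20, 20), date=SUMMER_DATE,
                  band_values=None) -> MultibandPass:
    """A pass with spatially constant reflectance (per band)."""
    bands = np.full((13, *shape), value, dtype=float)
    if band_values is not None:
        for i, v in enumerate(band_values):
            bands[i] = v
    return MultibandPass(bands, date, np.ones(shape, dtype=bool))


@pytest.fixture(scope="session")
def phenology():
    return make_phenology()


@pytest.fixture(scope="session")
def noise_free_phenology():
    return make_phenology(band_sd=0.0)


@pytest.fixture(scope="session")
def small_landscape():
    spec = LandscapeSpec(
        120, 120,
        {"reedbed": 0.02, "water": 0.08, "grassland": 0.65, "arable": 0.25},
        reed_patch_size=50.0,
        dem_params=DemParams(base_altitude=15.0, hill_amplitude=20.0),
        seed=11,
    )
    return generate_landscape(spec)


@pytest.fixture(scope="session")
def fixture_dataset():
    """The standard small end-to-end dataset (clouds, shifts, gain error)."""
    return make_fixture(size=150, seed=7)


@pytest.fixture(scope="session")
def clean_dataset(noise_free_phenology):
    """Noise-free, cloud-free, registered dataset: 2 summer + 2 winter passes."""
    spec = LandscapeSpec(
        100, 100,
        {"reedbed": 0.02, "water": 0.08, "grassland": 0.90},
        reed_patch_size=50.0, seed=5,
    )
    phen = make_phenology(classes=("reedbed", "water", "grassland"), band_sd=0.0)
    passes = [
        PassSpec(dt.date(2016, 6, 20)),
        PassSpec(dt.date(2016, 8, 20)),
        PassSpec(dt.date(2016, 12, 20)),
        PassSpec(dt.date(2017, 2, 20)),
    ]
    return generate_dataset(spec, passes, phen, TWO_SEASON_WINDOWS)
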