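import pytest

from greenspace import (
    WorldConfig,
    build_boundaries,
    build_exposure_table,
    compute_greenness,
    generate_health,
    generate_ndvi_stack,
    generate_region,
)


@pytest.fixture(scope="session")
def small_config():
    """A 20-county world small enough for every suite to rebuild quickly."""
    return WorldConfig(
        n_counties=20,
        counties_urban_fraction=0.25,
        blockgroups_per_county=9,
        county_size_m=8000.0,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_region(small_config)


@pytest.fixture(scope="session")
def small_stack(small_world, small_config):
    return generate_ndvi_stack(small_world, small_config)


@pytest.fixture(scope="session")
def small_greenness(small_stack):
    return compute_greenness(small_stack)


@pytest.fixture(scope="session")
def small_boundaries(small_world):
    return build_boundaries(small_world)


@pytest.fixture(scope="session")
def small_exposure(small_greenness, small_boundaries):
    return build_exposure_table(small_greenness, small_boundaries)


@pytest.fixture(scope="session")
def small_health(small_world, small_exposure, small_config):
    table, truth = generate_health(small_world, small_exposure, small_config)
    return table, truth
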