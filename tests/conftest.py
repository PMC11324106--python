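import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from slfspread import (
    CountyRecord,
    SimulationConfig,
    SyntheticSpec,
    build_region,
    generate_region,
    synthetic_parameters,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_record(fips, year=None, gc=1, pop=1000, highways=(), name=None, state="ZZ"):
    return CountyRecord(
        fips=fips,
        name=name or f"C{fips}",
        state=state,
        year_infested=year,
        garden_centers=gc,
        population=pop,
        highway_ids=frozenset(highways),
    )


@pytest.fixture
def path3_region():
    """3-county path c1 - c2 - c3; c1 infested 2014, c2 2015, c3 never."""
    records = [
        make_record("10001", year=2014),
        make_record("10002", year=2015),
        make_record("10003"),
    ]
    pairs = [("10001", "10002"), ("10002", "10003")]
    return build_region(records, pairs)


@pytest.fixture
def highway4_region():
    """4 counties in a path, the two ends also joined by an interstate."""
    records = [
        make_record("20001", year=2014, gc=10, pop=50_000, highways={80}),
        make_record("20002", gc=5, pop=20_000),
        make_record("20003", gc=5, pop=20_000),
        make_record("20004", gc=20, pop=10_000, highways={80}),
    ]
    pairs = [("20001", "20002"), ("20002", "20003"), ("20003", "20004")]
    return build_region(records, pairs)


@pytest.fixture
def grid_region():
    return generate_region(SyntheticSpec(grid_shape=(5, 5), n_highways=1, rng_seed=11))


@pytest.fixture
def grid_params(grid_region):
    return synthetic_parameters(grid_region, a=0.3)


@pytest.fixture
def quick_config(grid_region):
    return SimulationConfig(
        seed_fips=grid_region.fips_codes[12], horizon=4, n_runs=50, rng_seed=7
    )
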