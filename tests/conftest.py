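from dataclasses import replace
from datetime import date

import pandas as pd
import pytest

from masktrends.synthetic_data import (
    GeneratorParams,
    make_gazetteer,
    make_mandate_schedule,
    simulate_latent_prevalence,
    simulate_panel,
    simulate_tweets,
)


@pytest.fixture(scope="session")
def small_params() -> GeneratorParams:
    """Reduced-scale study: 24 counties / 6 states / 10 weeks, light streams."""
    return GeneratorParams(
        n_counties=24,
        n_states=6,
        n_weeks=10,
        users_per_county_week=120.0,
        min_users_per_county_week=0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_world(small_params):
    counties, overlaps = make_gazetteer(small_params)
    schedule = make_mandate_schedule(counties, small_params)
    return counties, overlaps, schedule


@pytest.fixture(scope="session")
def small_panel(small_params) -> pd.DataFrame:
    return simulate_panel(small_params)


@pytest.fixture(scope="session")
def small_stream(small_params, small_world) -> pd.DataFrame:
    counties, overlaps, schedule = small_world
    latent = simulate_latent_prevalence(counties, schedule, small_params)
    return simulate_tweets(counties, overlaps, latent, small_params)


@pytest.fixture(scope="session")
def fit_panel():
    """A panel big enough for a stable GLMM fit but quick to generate."""
    params = GeneratorParams(
        n_counties=60, n_states=12, n_weeks=10, users_per_county_week=600.0, seed=13
    )
    return params, simulate_panel(params)


@pytest.fixture()
def monday() -> date:
    return date(2020, 3, 2)


def tweak(params: GeneratorParams, **kwargs) -> GeneratorParams:
    return replace(params, **kwargs)
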