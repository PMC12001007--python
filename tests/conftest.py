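import dataclasses

import numpy as np
import pandas as pd
import pytest

from arcticmismatch.config import ScenarioConfig, ScenarioTruth
from arcticmismatch.simulate import (
    gen_chick_cohort,
    gen_pitfall_season,
    realized_snowmelt,
)


@pytest.fixture(scope="session")
def config() -> ScenarioConfig:
    return ScenarioConfig()


@pytest.fixture(scope="session")
def snowmelt(config):
    return realized_snowmelt(config)


@pytest.fixture(scope="session")
def field_years(config):
    return config.year_list[-2:]


@pytest.fixture(scope="session")
def chicks(config, snowmelt, field_years) -> pd.DataFrame:
    return pd.concat(
        [gen_chick_cohort(config, y, snowmelt=snowmelt) for y in field_years],
        ignore_index=True,
    )


@pytest.fixture(scope="session")
def pitfalls(config, snowmelt, field_years) -> pd.DataFrame:
    return pd.concat(
        [gen_pitfall_season(config, y, snowmelt=snowmelt) for y in field_years],
        ignore_index=True,
    )


@pytest.fixture(scope="session")
def sources_frame(config) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family": [s.family for s in config.source_isotopes],
            "d15n_mean": [s.d15n_mean for s in config.source_isotopes],
            "d15n_sd": [s.d15n_sd for s in config.source_isotopes],
        }
    )


def reseeded(config: ScenarioConfig, seed: int, **overrides) -> ScenarioConfig:
    return dataclasses.replace(config, seed=seed, **overrides)
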