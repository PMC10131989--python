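import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import keysleep as ks

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> ks.SimConfig:
    """A 12-participant week: fast but structurally complete."""
    return ks.SimConfig(n_participants=12, n_nights=7, seed=321)


@pytest.fixture(scope="session")
def small_cohort(small_config) -> ks.SimulatedCohort:
    return ks.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_paired(small_config, small_cohort):
    """Paired metric tables for the small cohort."""
    cfg = small_config
    dr = (cfg.start_date, cfg.start_date + dt.timedelta(days=cfg.n_nights - 1))
    kb, day = ks.extract_all_nights(small_cohort.events, date_range=dr,
                                    timezone=cfg.timezone)
    from helpers import diary_roundtrip
    dy = ks.derive_nights(diary_roundtrip(small_cohort.diaries))
    return ks.pair_nights(kb, dy, day)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
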