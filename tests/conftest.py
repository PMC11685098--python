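import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import curiomap as cm

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def open_room() -> cm.RoomGrid:
    return cm.generate_room(1, 0.0, room_id="open")


@pytest.fixture(scope="session")
def occluded_room() -> cm.RoomGrid:
    return cm.generate_room(2, 0.3, room_id="occluded")


@pytest.fixture(scope="session")
def small_cohort() -> cm.Cohort:
    """Agent-based cohort small enough for the unit-test budget."""
    cfg = cm.SimConfig(n_participants=6, n_rooms=4, duration_mean_s=15.0,
                       duration_sd_s=8.0, seed=7)
    return cm.generate_cohort(cfg)


@pytest.fixture(scope="session")
def linear_cohort() -> dict:
    """Known-coefficient cohort at the study's size (60 x 16)."""
    return cm.generate_linear_cohort(60, 16, seed=3)


@pytest.fixture(scope="session")
def linear_design(linear_cohort) -> pd.DataFrame:
    # the linear trial table already carries its composite column
    return cm.build_design(linear_cohort["trials"], traits=linear_cohort["traits"])


@pytest.fixture(scope="session")
def quick_settings() -> cm.SamplerSettings:
    return cm.SamplerSettings(chains=2, iterations=800)
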