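"""Shared fixtures: small simulated scenes with known truth."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pytest

from scarmap import GridSpec, MonthKey
from scarmap.synth import SimConfig, simulate_stack


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(96, 96, pixel_size=20.0)


@pytest.fixture(scope="session")
def burn_scene(small_grid):
    """One ~30-ha burn in 2019-09 plus a wet-soil confuser, no cloud."""
    cfg = SimConfig(
        grid=small_grid,
        months=[MonthKey(2019, m) for m in range(6, 13)],
        cloud_prob=0.0,
        n_burn_events=1,
        burn_size_range=(30.0, 30.0),
        burn_month_assignment={0: MonthKey(2019, 9)},
        n_confusers=1,
        confuser_size_range=(10.0, 10.0),
        hotspot_jitter_m=100.0,
        seed=42,
    )
    return simulate_stack(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
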