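"""Shared fixtures.

The expensive fixture is the noiseless volume bank (every phantom case
degraded under every system preset); it is computed once per session and
shared by the parameter-recovery, directional and monotonicity tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from stentbench.pipeline import (
    ExperimentConfig,
    PhantomCase,
    StentRole,
    default_cases,
    simulate_bank,
)
from stentbench.phantom import intertwined_pair_phantom, single_stent_phantom

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> ExperimentConfig:
    return ExperimentConfig()


@pytest.fixture(scope="session")
def bank(default_config):
    """Noiseless degraded volumes for all cases x presets (the heavy stage)."""
    return simulate_bank(default_config)


@pytest.fixture(scope="session")
def carotid_case() -> PhantomCase:
    return default_cases()[0]


@pytest.fixture(scope="session")
def overlap_pair_case() -> PhantomCase:
    """Femoral-like pair overlapping over the whole (short) volume."""
    spec = intertwined_pair_phantom(overlap_mm=2.52, stent_length_mm=2.52)
    return PhantomCase(
        name="pair_overlap",
        spec=spec,
        z_extent_mm=2.52,
        roles=(),
        distinction_z_window_mm=None,
    )


@pytest.fixture(scope="session")
def iliac_case() -> PhantomCase:
    return default_cases()[2]


@pytest.fixture(scope="session")
def small_config(carotid_case) -> ExperimentConfig:
    """A cheap two-preset, one-case configuration for pipeline/CLI tests."""
    return ExperimentConfig(
        master_seed=3,
        presets=("si_pcct_150", "eidct_150"),
        cases=(carotid_case,),
    )
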