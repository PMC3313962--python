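"""Shared fixtures: small, fast network configurations and cached runs.

The heavy defaults (N = 50, dt = 0.1 min, 9 + 7 days) are exercised by the
acceptance tests; unit and property tests use a reduced ensemble (N = 4,
dt = 0.01 h, 5 LD + 5 DD days) that keeps every qualitative feature of the
dynamics while integrating in well under a second.
"""

import numpy as np
import pytest

from clocknet import (ClockParams, LightSchedule, ModulationSpec,
                      NetworkConfig, simulate)

FAST_DT = 0.01


@pytest.fixture(scope="session")
def fast_config():
    """Small uncoupled noisy ensemble with a short 5 LD + 5 DD protocol."""
    return NetworkConfig(N=4, sigma=0.05, dt=FAST_DT,
                         schedule=LightSchedule(ld_days=5, dd_days=5), seed=11)


@pytest.fixture(scope="session")
def quiet_config(fast_config):
    """Deterministic, phase-aligned version of the fast ensemble."""
    return fast_config.with_(sigma=0.0, ic_sd=0.0)


@pytest.fixture(scope="session")
def quiet_run(quiet_config):
    return simulate(quiet_config)


@pytest.fixture(scope="session")
def noisy_run(fast_config):
    return simulate(fast_config)
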