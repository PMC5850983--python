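"""Shared fixtures: a seeded synergy generator, a short calibration session
and a calibrated model.

The short session uses compressed contraction timing (0.5 s ramps, 1 s
holds, 1 s rests) so unit tests stay fast; recovery-quality assertions that
need the full-length protocol build their own sessions.
"""

import numpy as np
import pytest

from emg2kin import (
    SimulatedUser,
    SynergyGenerator,
    TrainConfig,
    calibrate_session,
    generate_calibration_session,
    generate_target_set,
)

SEED = 7


@pytest.fixture(scope="session")
def generator():
    return SynergyGenerator(seed=SEED)


@pytest.fixture(scope="session")
def short_session(generator):
    session, truths = generate_calibration_session(
        generator, ramp_seconds=0.5, hold_seconds=1.0, rest_seconds=1.0
    )
    return session, truths


@pytest.fixture(scope="session")
def model(short_session):
    session, _ = short_session
    return calibrate_session(session, TrainConfig(seed=SEED))


@pytest.fixture(scope="session")
def targets():
    return generate_target_set(seed=SEED)


@pytest.fixture(scope="session")
def user():
    return SimulatedUser()


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
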