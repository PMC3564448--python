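"""Shared fixtures: one small simulated session reused across module tests.

The small session uses the full eight-block task structure at reduced block
sizes (28 laps) and a 12-cell roster so behavioral and ensemble machinery is
exercised end to end while the suite stays fast. Full-scale sessions live in
the acceptance tests only.
"""

import numpy as np
import pytest

from episodecode.session import (Session, simulate_session, prepare_session,
                                 build_trajectory_set)
from episodecode.taskmodel import MazeGeometry, TuningParams, TrackingParams

SMALL_BLOCKS = (("VD", 4), ("SA", 4), ("VD", 2), ("DA", 4),
                ("VD", 4), ("SA", 4), ("VD", 2), ("DA", 4))


@pytest.fixture(scope="session")
def geometry():
    return MazeGeometry()


@pytest.fixture(scope="session")
def small_session() -> Session:
    return simulate_session(
        blocks=SMALL_BLOCKS,
        tuning_params=TuningParams(n_cells=12, n_untuned=2, n_interneurons=1),
        seed=42)


@pytest.fixture(scope="session")
def small_prep(small_session):
    return prepare_session(small_session)


@pytest.fixture(scope="session")
def small_ts(small_prep):
    return build_trajectory_set(small_prep)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
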