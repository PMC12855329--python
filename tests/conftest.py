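import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pbac.agents import AgentParams, simulate_session
from pbac.task_engine import CourtGeometry, ExperimentDesign


@pytest.fixture(scope="session")
def geom() -> CourtGeometry:
    return CourtGeometry()


@pytest.fixture(scope="session")
def default_session():
    """One full closed-loop session, shared across read-only tests."""
    return simulate_session(AgentParams(seed=7), ExperimentDesign(), seed=7, participant_id="P01")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
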