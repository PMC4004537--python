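import logging

import numpy as np
import pytest

import betabind as bb
from betabind.config import SessionConfig

logging.getLogger("betabind").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def layout20():
    return bb.make_layout(20)


@pytest.fixture(scope="session")
def layout40():
    return bb.make_layout(40)


@pytest.fixture(scope="session")
def small_session(layout40):
    """One 120-trial session at generator defaults (40 sensors)."""
    cfg = SessionConfig(seed=42, n_runs=2)
    return cfg, bb.simulate_session(cfg, layout40, seed=42)


@pytest.fixture(scope="session")
def clean_session(layout40):
    """Artifact-free 120-trial session with balanced percepts."""
    cfg = SessionConfig(seed=7, n_runs=2, artifact_rate=0.0,
                        unclassified_rate=0.0)
    return cfg, bb.simulate_session(cfg, layout40, seed=7)
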