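"""Shared fixtures.

The canonical model, its normoxic steady state and the standard hypoxia time
courses are session-scoped: they are deterministic and every module asserts
against the same trajectories, so they are integrated once.
"""

import numpy as np
import pytest

from hifmir import (
    Protocol,
    build_canonical_model,
    find_normoxic_steady_state,
    run_protocol,
)


@pytest.fixture(scope="session")
def model():
    return build_canonical_model()


@pytest.fixture(scope="session")
def steady_state(model):
    return find_normoxic_steady_state(model)


@pytest.fixture(scope="session")
def tc_hypoxia_2pct(model):
    """48 h at 2% O2, 1-minute resolution — the workhorse trajectory."""
    return run_protocol(model, Protocol(o2_percent=2.0, duration=2880.0))


@pytest.fixture(scope="session")
def tc_normoxia(model):
    """48 h at 21% O2 (steady-state invariance check)."""
    return run_protocol(model, Protocol(o2_percent=21.0, duration=2880.0,
                                        output_every=10.0))


@pytest.fixture(scope="session")
def tc_hypoxia_1pct_8h(model):
    return run_protocol(model, Protocol(o2_percent=1.0, duration=480.0))
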