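import numpy as np
import pytest

from stereozest import (
    SimulatedObserver,
    StaircaseConfig,
    TASK_2AFC,
    TASK_4AFC,
    run_updown,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def standard_2afc():
    return SimulatedObserver.standard(TASK_2AFC)


@pytest.fixture
def standard_4afc():
    return SimulatedObserver.standard(TASK_4AFC)


@pytest.fixture
def short_session(standard_4afc):
    """An 80-trial simulated up/down session (fixed seed)."""
    return run_updown(standard_4afc, StaircaseConfig(n_trials=80),
                      np.random.default_rng(7))
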