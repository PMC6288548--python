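import numpy as np
import pytest

from eventarena import (AgentParams, ArenaGeometry, build_participant,
                        simulate_participant, summarize_trials)


@pytest.fixture(scope="session")
def geometry():
    return ArenaGeometry()


@pytest.fixture(scope="session")
def participant_config(geometry):
    return build_participant(36, geometry, seed=101)


@pytest.fixture(scope="session")
def small_config(geometry):
    return build_participant(12, geometry, seed=202)


@pytest.fixture(scope="session")
def simulated_trials(participant_config):
    """One full-schedule participant, trajectory mode (session cached)."""
    return simulate_participant(participant_config, AgentParams(seed=7))


@pytest.fixture(scope="session")
def trial_metrics(simulated_trials):
    return summarize_trials(simulated_trials)
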