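import numpy as np
import pytest

import beadtask as bt
from beadtask.cohort import AgentSpec, simulate_participant
from beadtask.data import ParticipantData


@pytest.fixture(scope="session")
def design():
    return bt.build_design(seed=1)


@pytest.fixture(scope="session")
def neglect_params():
    """The illustrative base-rate-neglecting agent (omega1 = 0.88, omega2 = 0.51)."""
    return bt.WeightedBayesParams(0.88, 0.51)


def make_participant(design, agent_type, params, late_noise_sd=0.0, lapse_rate=0.0, seed=0, pid=0):
    agent = AgentSpec(agent_type, params, late_noise_sd, lapse_rate)
    frame = simulate_participant(design, agent, np.random.default_rng(seed), pid)
    return ParticipantData.from_frame(frame)


@pytest.fixture(scope="session")
def ideal_participant(design):
    return make_participant(design, "ideal", bt.WeightedBayesParams.ideal())


@pytest.fixture(scope="session")
def neglect_participant(design, neglect_params):
    return make_participant(design, "weighted_bayes", neglect_params)
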