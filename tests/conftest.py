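"""Shared fixtures: small synthetic sessions generated at test time."""

import numpy as np
import pytest

from mentalnav.observer import ObserverParams
from mentalnav.synthetic import (
    PopulationSpec,
    gen_behavior_session,
    gen_spike_session,
    make_class_spec,
)
from mentalnav.task import enumerate_conditions


@pytest.fixture(scope="session")
def long_conditions():
    """Conditions requiring navigation over at least three landmarks."""
    return [c for c in enumerate_conditions() if c.distance >= 3]


@pytest.fixture(scope="session")
def behavior_trials(long_conditions):
    """40 long-distance trials from a low-noise observer."""
    obs = ObserverParams(w_m=0.05, w_p=0.05, model_kind="subscalar")
    return gen_behavior_session(obs, conditions=long_conditions, n_trials=40, seed=1)


@pytest.fixture(scope="session")
def periodic_neuron(behavior_trials):
    pop = PopulationSpec([make_class_spec("periodic")], seed=2)
    return gen_spike_session(pop, behavior_trials, seed=3)[0]


@pytest.fixture(scope="session")
def untuned_neuron(behavior_trials):
    pop = PopulationSpec([make_class_spec("untuned", baseline=20.0)], seed=4)
    return gen_spike_session(pop, behavior_trials, seed=5)[0]
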