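import numpy as np
import pytest

from vsdd import BehaviorParams, NeuronParams, simulate_behavior, simulate_neuron
from vsdd.config import AnalysisConfig


@pytest.fixture(scope="session")
def desk_config() -> AnalysisConfig:
    """Desk-scale classifier configuration (coarser step, fewer shuffles)."""
    return AnalysisConfig(step_ms=10, n_shuffle=200, seed=0)


@pytest.fixture(scope="session")
def behavior_session():
    """One default behavioral session (300 trials, logit 1.2*(V-4))."""
    return simulate_behavior(BehaviorParams(), seed=42)


@pytest.fixture(scope="session")
def transition_neuron(behavior_session):
    """Spike trains of a default value-then-choice transition neuron."""
    return simulate_neuron(NeuronParams(), behavior_session, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
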