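"""Shared fixtures: simulated sessions and preprocessed epoch sets.

Session-scoped so the expensive continuous simulations run once; tests must
not mutate fixture data in place.
"""

import numpy as np
import pytest

from brakesense.evaluate import prepare_offline_epochs
from brakesense.preprocess import PreprocConfig
from brakesense.simulate import SimulationConfig, simulate_session


@pytest.fixture(scope="session")
def default_session():
    """Full default-conditions subject: 60 trials, 30 hard, 1000 Hz."""
    return simulate_session(SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def default_preproc():
    return PreprocConfig()


@pytest.fixture(scope="session")
def default_epochs(default_session, default_preproc):
    """90 balanced preprocessed offline samples from the default subject."""
    epochs, suppressor = prepare_offline_epochs(default_session, default_preproc, seed=11)
    return epochs


@pytest.fixture(scope="session")
def small_epochs():
    """Cheap 18-epoch set (12 trials) for model-plumbing tests."""
    cfg = SimulationConfig(seed=7, n_trials=12, n_hard_trials=6)
    session = simulate_session(cfg)
    pre = PreprocConfig(artifact_suppression="off")
    epochs, _ = prepare_offline_epochs(session, pre, seed=3)
    return epochs


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
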