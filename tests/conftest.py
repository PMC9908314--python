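import numpy as np
import pytest
from hypothesis import settings

import tipm

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_session():
    """A small simulated step session with heterogeneous cells."""
    neurons = tipm.make_population(6, rng=11)
    cfg = tipm.SimulationConfig(tipm.default_protocols(), neurons, seed=11)
    traces, gt = tipm.simulate_experiment(cfg)
    return cfg, traces, gt


@pytest.fixture(scope="session")
def small_peaks(small_session):
    _, traces, _ = small_session
    return tipm.extract_peaks(tipm.normalize(traces))


@pytest.fixture(scope="session")
def noise_free_session():
    """Noise-free plateau cells: the deterministic forward model end to end."""
    neurons = tipm.make_population(4, rng=2, noise_sd=0.0, decay_class="plateau")
    cfg = tipm.SimulationConfig(tipm.default_protocols(), neurons, seed=2)
    traces, gt = tipm.simulate_experiment(cfg)
    return cfg, traces, gt
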