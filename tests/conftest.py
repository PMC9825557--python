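import numpy as np
import pytest

from amygaze import synth


@pytest.fixture(scope="session")
def truth():
    return synth.default_ground_truth()


@pytest.fixture(scope="session")
def symmetric_truth():
    return synth.default_ground_truth(symmetric=True)


@pytest.fixture(scope="session")
def small_design():
    return synth.make_design(synth.DesignSpec(n_participants=2, trials_per_block=20, seed=7))


@pytest.fixture(scope="session")
def behaviour_table(small_design, truth):
    return synth.simulate_behaviour(small_design, truth, seed=7)


@pytest.fixture(scope="session")
def latency_table(truth):
    design = synth.make_design(synth.DesignSpec(n_participants=4, trials_per_block=25, seed=9))
    return synth.simulate_latency_cohort(design, truth, seed=9)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
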