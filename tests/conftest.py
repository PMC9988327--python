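import numpy as np
import pytest

import sidedmri as sd


@pytest.fixture(scope="session")
def phantom_spec():
    return sd.default_phantom()


@pytest.fixture(scope="session")
def phantom_gradients(phantom_spec):
    return sd.make_gradients(phantom_spec.shells, seed=1)


@pytest.fixture(scope="session")
def phantom_truth(phantom_spec, phantom_gradients):
    truth, _ = sd.synthesize(phantom_spec, phantom_gradients)
    return truth


@pytest.fixture(scope="session")
def default_dictionary(phantom_gradients):
    return sd.build_dictionary(phantom_gradients)


@pytest.fixture(scope="session")
def default_grouping():
    # 12 slices at SMS factor 3 -> 4 slice groups, divides N_Q = 40
    return sd.make_grouping(12, 3)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
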