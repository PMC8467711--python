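import numpy as np
import pytest

from ctirecon import multib_fit, synthetic_data


def random_spd(rng, scale=1e-3):
    a = rng.normal(size=(3, 3))
    return (a @ a.T) * scale + np.eye(3) * scale * 0.1


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def phantom1():
    return synthetic_data.make_phantom_preset("phantom1", (24, 24, 6))


@pytest.fixture(scope="session")
def phantom2():
    return synthetic_data.make_phantom_preset("phantom2", (24, 24, 6))


@pytest.fixture(scope="session")
def phantom1_stack(phantom1):
    return synthetic_data.simulate_dwi(phantom1)


@pytest.fixture(scope="session")
def phantom1_fit(phantom1_stack):
    return multib_fit.assemble_fast_slow(phantom1_stack)


@pytest.fixture(scope="session")
def brain():
    truth, masks = synthetic_data.make_brain((48, 48, 6), seed=3)
    return truth, masks


@pytest.fixture(scope="session")
def brain_stack(brain):
    truth, _ = brain
    return synthetic_data.simulate_dwi(truth)


@pytest.fixture(scope="session")
def brain_fit(brain_stack):
    return multib_fit.assemble_fast_slow(brain_stack)


@pytest.fixture(scope="session")
def brain_dti(brain_stack):
    return multib_fit.fit_dti(brain_stack)
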