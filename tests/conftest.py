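import numpy as np
import pytest

import h2opet as h


@pytest.fixture(scope="session")
def schedule():
    return h.FrameSchedule.water_default()


@pytest.fixture(scope="session")
def input_fn():
    return h.make_input_function()


@pytest.fixture(scope="session")
def basis():
    return h.SpectralBasis.default()


@pytest.fixture(scope="session")
def default_params():
    return h.OneTissueParams(K1=0.8, k2=0.4, V0=0.05)


@pytest.fixture(scope="session")
def noisefree_sim():
    """Noise-free default phantom study (shared: simulation is deterministic)."""
    return h.simulate_patient(h.PhantomSpec(sigma0=0.0, seed=7))
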