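import logging

import numpy as np
import pytest

import glycosim as g

logging.getLogger("glycosim").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def reference_model():
    return g.build_reference_model()


@pytest.fixture(scope="session")
def reference_steady(reference_model):
    res = g.integrate_to_steady_state(reference_model)
    assert res.converged
    return res


@pytest.fixture(scope="session")
def default_grid():
    return np.arange(2.0, 12.01, 0.5)


@pytest.fixture(scope="session")
def reference_sweep(reference_model, default_grid):
    return g.glucose_sweep(reference_model, default_grid)


@pytest.fixture
def toy_spec():
    return g.ToyModelSpec(k0=1.0, k1=2.0, k2=4.0)


@pytest.fixture
def toy_model(toy_spec):
    return g.generate_toy_chain(toy_spec)


@pytest.fixture(scope="session")
def ko_scenario_zero_noise():
    return g.make_ko_scenario(n_per_group=6, seed=0, noise_sigma=0.0)
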