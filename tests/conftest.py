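import numpy as np
import pytest

from meadowpath import geostat, synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_field(rng):
    """A 40-point GP realization on the study-sized domain."""
    params = geostat.GPParams(beta=2.0, sigma2=1.0, phi=5.0, tau2_rel=0.2)
    loc = rng.uniform((0, 0), (40, 50), size=(40, 2))
    return synth.simulate_grf(loc, params, seed=7)


@pytest.fixture
def tiny_grid():
    return geostat.ParameterGrid(
        phi_support=np.array([2.0, 5.0, 12.0]),
        tau2rel_support=np.array([0.0, 0.2, 0.5]),
    )


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study at the default shape (234 plants, 71 sites)."""
    cfg = synth.default_truth_config(seed=2024)
    plants, env, surfaces, cfg = synth.generate_study(cfg)
    return plants, env, surfaces, cfg
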