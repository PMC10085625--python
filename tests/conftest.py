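import warnings

import numpy as np
import pytest

from hcam.model import fit
from hcam.simulate import ScenarioSpec, generate

# rank-deficiency / no-variation warnings are expected on tiny fixtures
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_scenario():
    """A small scenario-A dataset with known truth (H=40, n_h=25)."""
    spec = ScenarioSpec(scenario="A", H=40, n_h=25, re_dist="normal", seed=42)
    data, truth = generate(spec)
    return data, truth


@pytest.fixture(scope="session")
def small_fit(small_scenario):
    """A Gaussian-random-effect fit of the small dataset, shared read-only."""
    data, _ = small_scenario
    return fit(data, model="hcam", K_grid=(0,), n_quad=21)


@pytest.fixture(scope="session")
def small_zib():
    """A small zero-inflated dataset and its two-component fit."""
    spec = ScenarioSpec(scenario="ZIB", H=30, n_h=20, theta=-2.0, seed=7)
    data, truth = generate(spec)
    res = fit(data, model="zib", K_grid=(0,), n_quad=21)
    return data, truth, res


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
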