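import numpy as np
import pytest

from scatterlearn.doe import generate_design
from scatterlearn.pipeline import build_training_set
from scatterlearn.simulator import OpticsConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_training():
    """A 40-point simulated training set at a modest photon budget.

    Shared by feature/pipeline tests that only need a realistic feature
    table, not low Monte Carlo noise.
    """
    design = generate_design(40)
    optics = OpticsConfig(n_photons=30_000)
    return build_training_set(design, optics, base_seed=11)


@pytest.fixture(scope="session")
def gaussian_image():
    """Synthetic isotropic Gaussian pattern with a known radial width."""
    yy, xx = np.indices((100, 100))
    w = 10.0
    img = np.exp(-(((yy - 49.5) ** 2 + (xx - 49.5) ** 2) / (2 * w * w)))
    return img, w
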