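import numpy as np
import pytest

from fretquant.synthetic import SyntheticScenario


@pytest.fixture
def scenario() -> SyntheticScenario:
    """Default study-condition scenario with a compact image geometry.

    Parameter truth (sensor variants, noise levels, bleedthrough, decay
    model) is the default; only the FOV raster is shrunk to 128x128 with 12
    cells so image-based unit tests stay fast.
    """
    sc = SyntheticScenario(seed=7)
    sc.image.shape = (128, 128)
    sc.image.n_cells = 12
    return sc


@pytest.fixture
def full_scenario() -> SyntheticScenario:
    """Scenario at the full default geometry (512x512, 55 cells per FOV)."""
    return SyntheticScenario(seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
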