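import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from scattercyte import OpticalConfig, build_lookup
from scattercyte.pipeline import toy_grid


@pytest.fixture(scope="session")
def default_optics() -> OpticalConfig:
    return OpticalConfig()


@pytest.fixture(scope="session")
def toy_grid_spec():
    return toy_grid()


@pytest.fixture(scope="session")
def toy_table(toy_grid_spec, default_optics):
    """240-row lookup table, small enough for exhaustive brute-force checks."""
    return build_lookup(toy_grid_spec, default_optics)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
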