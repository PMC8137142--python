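import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from transperon.config import DetectionParams, SimulationConfig
from transperon.simulate import generate_cell_geometry, simulate_spot_fields


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        n_cells=3,
        spots_per_cell_mean=8,
        true_rho=0.5,
        jitter_sigma=0.05,
        cell_radius=(1.6, 2.0, 2.0),
        rng_seed=1,
    )


@pytest.fixture(scope="session")
def small_geometry(small_cfg):
    return generate_cell_geometry(small_cfg)


@pytest.fixture(scope="session")
def small_truths(small_cfg, small_geometry):
    return simulate_spot_fields(small_geometry, small_cfg)


@pytest.fixture
def default_params():
    return DetectionParams()
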