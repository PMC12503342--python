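import numpy as np
import pytest

from spami.containers import SpatialOmicsPair
from spami.pipeline import _preprocess_pair
from spami.simulate import SimulationConfig, simulate_pair


@pytest.fixture(scope="session")
def small_pair() -> SpatialOmicsPair:
    """A 15x15 RNA+ADT simulation with mild noise (shared, read-only)."""
    return simulate_pair(SimulationConfig(grid_shape=(15, 15), noise_sd=0.5, seed=7))


@pytest.fixture(scope="session")
def small_processed(small_pair) -> SpatialOmicsPair:
    fm1, fm2 = _preprocess_pair(small_pair, {"d_out": 30})
    return SpatialOmicsPair(
        X1=fm1.values, X2=fm2.values, coords=small_pair.coords,
        modalities=small_pair.modalities, labels=small_pair.labels,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
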