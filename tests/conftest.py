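import numpy as np
import pytest

from hicpoly.preprocess import ContactMap
from hicpoly.simulator import PolymerConfig


def random_symmetric_positive(m: int, seed: int = 0) -> np.ndarray:
    """Strictly positive symmetric matrix with Hi-C-like distance decay."""
    rng = np.random.default_rng(seed)
    base = rng.random((m, m)) + 0.1
    sym = 0.5 * (base + base.T)
    i, j = np.indices((m, m))
    decay = 1.0 / (1.0 + np.abs(i - j))
    return sym * decay * 100.0


@pytest.fixture
def raw_map_64() -> ContactMap:
    return ContactMap(random_symmetric_positive(64, seed=1))


@pytest.fixture
def raw_map_32() -> ContactMap:
    return ContactMap(random_symmetric_positive(32, seed=2))


@pytest.fixture
def fast_poly_cfg() -> PolymerConfig:
    """Small sampling budget for unit tests."""
    return PolymerConfig(
        m=32,
        n_structures=200,
        n_equilibration_sweeps=50,
        n_sweeps_between_samples=2,
        seed=11,
    )
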