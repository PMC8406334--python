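import numpy as np
import pytest

from irca.core import CellMeta, Ramanome, SpectralAxis
from irca.synth import get_preset, simulate_ramanome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_axis():
    return SpectralAxis(600.0 + np.arange(101))  # 600..700


@pytest.fixture
def random_ramanome(rng, small_axis):
    """10 cells x 101 features of positive random intensities."""
    m = rng.uniform(0.1, 2.0, size=(10, len(small_axis)))
    cells = [CellMeta(f"c{i}", "rand") for i in range(10)]
    return Ramanome(small_axis, m, cells, {"ramanome_id": "rand"})


@pytest.fixture(scope="session")
def late_pst_ramanome():
    """60-cell synthetic ramanome at the late conversion state
    (planted starch-TAG latent correlation -0.8, 5% noise)."""
    sc = get_preset("pst").state_at(192.0)
    return simulate_ramanome(sc, n_cells=60, seed=7, ramanome_id="late_pst")
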