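import numpy as np
import pytest

from hyperplex.io import CellTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_table(rng):
    """Small two-population table: marker M0 separates the groups cleanly."""
    n = 200
    group = np.repeat([0, 1], n // 2)
    markers = np.exp(rng.normal(0.0, 0.3, (n, 3)))
    markers[group == 1, 0] = np.exp(rng.normal(2.5, 0.3, n // 2))
    return CellTable(
        cell_id=np.arange(n),
        x=rng.uniform(0, 100, n),
        y=rng.uniform(0, 100, n),
        markers=markers,
        marker_names=["M0", "M1", "M2"],
    ), group
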