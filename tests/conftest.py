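import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))   # make oracles importable

from specattn.preprocess import SpectraDataset, WavelengthGrid  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    return WavelengthGrid(np.linspace(400.0, 700.0, 16))


@pytest.fixture
def tiny_dataset(small_grid, rng):
    """Two well-separated classes on 16 bands, 20 samples each."""
    t0 = np.linspace(0.2, 0.4, 16)
    t1 = np.linspace(0.7, 0.5, 16)
    X = np.vstack([t0 + 0.01 * rng.standard_normal((20, 16)),
                   t1 + 0.01 * rng.standard_normal((20, 16))])
    y = np.repeat([0, 1], 20)
    return SpectraDataset(X, y, small_grid, ["a", "b"], "VNIR")
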