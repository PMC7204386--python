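import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose _oracles

from neuromorph import BinaryMask, LabelVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def solid_cube_mask():
    """10^3 solid cube embedded in a 14^3 lattice, 1 mm isotropic."""
    data = np.zeros((14, 14, 14), dtype=bool)
    data[2:12, 2:12, 2:12] = True
    return BinaryMask(data, np.ones(3))


@pytest.fixture
def random_label_volume(rng):
    data = rng.integers(0, 4, size=(8, 8, 8))
    return LabelVolume(data, np.array([1.2, 0.93, 0.93]))
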