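import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the brute-force oracle helper

from topotsa import band_preset


@pytest.fixture(scope="session")
def alpha_band():
    return band_preset("alpha")


@pytest.fixture(scope="session")
def square_distance():
    """Unit square under L-infinity-ish metric: sides 1, diagonals 1.5."""
    return np.array(
        [
            [0.0, 1.0, 1.5, 1.0],
            [1.0, 0.0, 1.0, 1.5],
            [1.5, 1.0, 0.0, 1.0],
            [1.0, 1.5, 1.0, 0.0],
        ]
    )
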