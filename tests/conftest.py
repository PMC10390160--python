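import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mousehrv import generate_rr_series, group_preset


@pytest.fixture(scope="session")
def kx_rr():
    """One 300 s ketamine+xylazine-preset tachogram, reused across tests."""
    return generate_rr_series(group_preset("KX").modulation, duration=300.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
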