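import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from quasicrm import (
    DEFAULT_SKELETONS,
    ETScale,
    ModelEnsemble,
    TrialData,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20140529)


@pytest.fixture
def scale():
    return ETScale()


@pytest.fixture
def ensemble3():
    """The three reconstructed benchmark skeletons as a uniform-prior ensemble."""
    return ModelEnsemble.from_skeletons(DEFAULT_SKELETONS)


@pytest.fixture
def small_data():
    """A hand-sized mixed-grade dataset over six doses."""
    records = [(1, 0), (2, 1), (2, 0), (3, 2), (3, 1), (4, 3), (4, 2), (3, 0)]
    return TrialData.from_records(records, n_doses=6)
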