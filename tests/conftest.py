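import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from antibunch import HistogramFormat, ThreeLevelParams


@pytest.fixture
def fmt() -> HistogramFormat:
    return HistogramFormat()


@pytest.fixture
def toy_fmt() -> HistogramFormat:
    """A 3-bin toy format used by the stream-oracle comparisons."""
    return HistogramFormat(n_bins=3, span=30.0, zero_bin_index=1)


@pytest.fixture
def ideal_params() -> ThreeLevelParams:
    return ThreeLevelParams(a1=1.0, a2=0.0, t1=25.0, t2=100.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
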