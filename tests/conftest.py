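import numpy as np
import pytest

from phagoquant import CellCensus


@pytest.fixture
def simple_census() -> CellCensus:
    """Small hand-checkable census: 30 apoptotic cells, half engulfed."""
    return CellCensus(
        sample_id="s1",
        group="control",
        apo_total=30,
        apo_phagocytosed=15,
        microglia_total=100,
        pouch_histogram={1: 15, 2: 5},
        region_volume_mm3=0.05,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
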