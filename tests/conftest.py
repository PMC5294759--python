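import numpy as np
import pytest

from sirnapred.core_data import Dataset, SiRNARecord
from sirnapred.features import NearestNeighborTable

#: Published per-threshold PCC of the original 230-feature model, used to
#: replay the halving-then-bisection search against a fixed oracle.
REFERENCE_TRACE_PCC = {
    230: 0.705,
    115: 0.713,
    57: 0.722,
    28: 0.712,
    42: 0.720,
    49: 0.721,
    53: 0.721,
    55: 0.719,
    56: 0.721,
}

REFERENCE_VISITED_K = [230, 115, 57, 28, 42, 49, 53, 55, 56]
REFERENCE_SELECTED_K = 57


@pytest.fixture(scope="session")
def nn_table() -> NearestNeighborTable:
    return NearestNeighborTable.default()


@pytest.fixture
def uniform_table() -> NearestNeighborTable:
    """Synthetic table with every step worth the same increment."""
    steps = {a + b: -1.5 for a in "ACGU" for b in "ACGU"}
    return NearestNeighborTable(increments=steps, version="uniform-synthetic")


@pytest.fixture
def toy_dataset() -> Dataset:
    """Four hand-written records with activities on both sides of 0.7."""
    return Dataset(
        records=[
            SiRNARecord("r1", "UUACGUACGUACGUACGUACG", 0.9, "CGUACGUACGUACGUACGUAAGGG"),
            SiRNARecord("r2", "UUAAAAAAAAAAAAAAAAAAA", 0.8, "UUUUUUUUUUUUUUUUUUUAAGGG"),
            SiRNARecord("r3", "GGACGUACGUACGUACGUACG", 0.2, "CGUACGUACGUACGUACGUCCGGG"),
            SiRNARecord("r4", "GGCCCCCCCCCCCCCCCCCCC", 0.1, "GGGGGGGGGGGGGGGGGGGCCGGG"),
        ],
        name="toy",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230917)
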