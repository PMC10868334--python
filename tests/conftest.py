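import numpy as np
import pytest

from svglrt import CountMatrix, SpotTable


@pytest.fixture
def toy_counts() -> CountMatrix:
    # 5 spots x 4 genes; gene totals 15, 2, 40, 0
    counts = np.array(
        [
            [3, 0, 10, 0],
            [4, 1, 5, 0],
            [2, 0, 9, 0],
            [5, 1, 8, 0],
            [1, 0, 8, 0],
        ]
    )
    return CountMatrix(
        counts,
        [f"s{i}" for i in range(5)],
        ["gA", "gB", "gC", "gD"],
    )


@pytest.fixture
def two_cluster_spots() -> SpotTable:
    return SpotTable(
        ["s0", "s1", "s2", "s3"],
        [0.0, 1.0, 0.0, 1.0],
        [0.0, 0.0, 1.0, 1.0],
        ["A", "A", "B", "B"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
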