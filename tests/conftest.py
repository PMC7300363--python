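import numpy as np
import pytest

from magevo import BinaryContentMatrix, parse_newick


@pytest.fixture
def four_tip_tree():
    return parse_newick("((A:0.3,B:0.7)X:0.5,(C:0.2,D:0.9)Y:0.4)R;")


@pytest.fixture
def four_tip_matrix():
    rng = np.random.default_rng(42)
    cells = rng.integers(0, 2, size=(4, 8))
    cells[:, 0] = [1, 1, 1, 1]  # include constant columns too
    cells[:, 1] = [0, 0, 0, 0]
    return BinaryContentMatrix.from_arrays(
        ["A", "B", "C", "D"], [f"OG{i}" for i in range(8)], cells)
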