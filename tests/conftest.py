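import numpy as np
import pandas as pd
import pytest

from comecol.core_io import OtuTable, PhyloTree, SampleMetadata


@pytest.fixture
def tiny_table():
    """3 taxa x 2 samples, no zeros."""
    counts = np.array([[5, 3], [2, 7], [1, 4]])
    return OtuTable(counts, ["t1", "t2", "t3"], ["s1", "s2"])


@pytest.fixture
def small_table():
    """5 taxa x 4 samples with some zeros; all row totals positive."""
    counts = np.array(
        [
            [10, 0, 3, 1],
            [0, 5, 2, 8],
            [7, 7, 0, 0],
            [1, 2, 3, 4],
            [0, 0, 9, 2],
        ]
    )
    return OtuTable(counts, [f"t{i}" for i in range(5)], [f"s{j}" for j in range(4)])


@pytest.fixture
def star_tree_4():
    """Star tree over 4 tips with unit branches."""
    return PhyloTree.from_newick("(t0:1,t1:1,t2:1,t3:1);")


@pytest.fixture
def caterpillar_tree():
    return PhyloTree.from_newick("(A:1,(B:1,C:1):1);")


@pytest.fixture
def two_group_metadata():
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": ["s0", "s1", "s2", "s3"],
                "group": ["a", "a", "b", "b"],
            }
        )
    )
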