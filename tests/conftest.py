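import numpy as np
import pandas as pd
import pytest

import brewassembly as ba


@pytest.fixture
def balanced_tree():
    """((A:1,B:1):1,(C:1,D:1):1); — patristic d(A,B)=2, d(A,C)=4."""
    return ba.read_tree("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def balanced_dist(balanced_tree):
    return ba.patristic_matrix(balanced_tree, ["A", "B", "C", "D"])


@pytest.fixture
def small_table():
    df = pd.DataFrame(
        [[5, 3, 2, 0], [1, 0, 4, 2], [4, 0, 0, 3]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "t3", "t4"],
    )
    return ba.CountTable(df)


def make_table(counts, samples=None, taxa=None):
    counts = np.asarray(counts, dtype=np.int64)
    samples = samples or [f"s{i+1}" for i in range(counts.shape[0])]
    taxa = taxa or [f"t{j+1}" for j in range(counts.shape[1])]
    return ba.CountTable(pd.DataFrame(counts, index=samples, columns=taxa))
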