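import numpy as np
import pandas as pd
import pytest

from soilfungnet import CommunityMatrix, SampleMeta


def make_matrix(array, sample_ids=None, otu_ids=None, samples=None) -> CommunityMatrix:
    array = np.asarray(array)
    n, j = array.shape
    sample_ids = sample_ids or [f"s{i+1}" for i in range(n)]
    otu_ids = otu_ids or [f"OTU_{k+1:02d}" for k in range(j)]
    counts = pd.DataFrame(array, index=sample_ids, columns=otu_ids)
    return CommunityMatrix(counts, samples)


def make_meta(sample_id, depth_class="d1", depth_cm=0.0, x=0.0, rep=1, control=False):
    return SampleMeta(
        sample_id=sample_id,
        depth_class=depth_class,
        depth_value_cm=depth_cm,
        horizontal_position_m=x,
        replicate_id=rep,
        is_negative_control=control,
    )


@pytest.fixture
def depth_block_matrix():
    """8 samples over 2 depths; OTU_01 prefers depth d1, OTU_02 is everywhere."""
    counts = np.array(
        [
            [5, 3, 0, 1],
            [2, 4, 0, 0],
            [7, 2, 1, 0],
            [3, 5, 0, 2],
            [0, 6, 2, 0],
            [0, 3, 1, 1],
            [0, 2, 3, 0],
            [0, 4, 0, 2],
        ]
    )
    samples = [
        make_meta(f"s{i+1}", "d1" if i < 4 else "d2", 2.0 if i < 4 else -3.0, x=float(i))
        for i in range(8)
    ]
    return make_matrix(counts, samples=[s for s in samples])
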