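import numpy as np
import pandas as pd
import pytest

from featherbiome.containers import DistMatrix, OtuTable, SampleMetadata
from featherbiome.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """One compact synthetic study shared across read-only tests."""
    cfg = SimConfig(seed=11, n_otus=120, n_host_trees=6)
    return simulate_study(cfg)


@pytest.fixture()
def tiny_table():
    return OtuTable(
        pd.DataFrame(
            [[5, 0, 3], [1, 3, 4], [2, 2, 2]],
            index=["s1", "s2", "s3"],
            columns=["o1", "o2", "o3"],
        )
    )


@pytest.fixture()
def tiny_metadata():
    return SampleMetadata(
        pd.DataFrame(
            {
                "species": ["AA", "AA", "LL"],
                "locality": ["L1", "L2", "L1"],
                "lat": [49.0, 49.5, 49.0],
                "lon": [15.0, 16.0, 15.0],
            },
            index=["s1", "s2", "s3"],
        )
    )


def euclidean_dm(points, labels=None) -> DistMatrix:
    from scipy.spatial.distance import pdist, squareform

    points = np.asarray(points, dtype=float)
    labels = labels or [f"s{i}" for i in range(len(points))]
    return DistMatrix(list(labels), squareform(pdist(points)))
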