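import numpy as np
import pandas as pd
import pytest

from crosspredict.core_io import GenotypeMatrix, PhenotypeTable
from crosspredict.linkage import LinkageMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genotypes():
    """3 samples x 4 markers with one missing call."""
    calls = np.array(
        [
            [1.0, -1.0, 1.0, np.nan],
            [-1.0, -1.0, 1.0, 1.0],
            [1.0, 1.0, 1.0, -1.0],
        ]
    )
    return GenotypeMatrix(["s1", "s2", "s3"], ["m1", "m2", "m3", "m4"], calls)


@pytest.fixture
def two_chromosome_map():
    """5 + 4 markers on two chromosomes with irregular spacing."""
    rows = [
        ("a1", "1", 0.0), ("a2", "1", 12.5), ("a3", "1", 30.0),
        ("a4", "1", 55.0), ("a5", "1", 90.0),
        ("b1", "2", 0.0), ("b2", "2", 20.0), ("b3", "2", 20.0), ("b4", "2", 75.0),
    ]
    return LinkageMap(
        pd.DataFrame(rows, columns=["marker", "chromosome", "position_cM"])
    )


def random_parents(rng, marker_ids):
    """Two random inbred parent vectors over the given markers."""
    p1 = rng.choice([-1.0, 1.0], size=len(marker_ids))
    p2 = rng.choice([-1.0, 1.0], size=len(marker_ids))
    return p1, p2


@pytest.fixture
def training_data(rng):
    """Small complete training set with a known additive architecture."""
    n, p = 40, 60
    calls = rng.choice([-1.0, 1.0], size=(n, p))
    beta = rng.normal(0, 0.3, p)
    y = 7.0 + calls @ beta + rng.normal(0, 0.5, n)
    g = GenotypeMatrix(
        [f"s{i:02d}" for i in range(n)], [f"m{j:02d}" for j in range(p)], calls
    )
    return g, PhenotypeTable(g.sample_ids, y), beta
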