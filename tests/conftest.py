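import numpy as np
import pytest

from pcaplanes import BucketTable, FeatureKey


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(values, rts=None, mzs=None, strain_ids=None):
    """Build a BucketTable from a plain matrix with auto-generated keys."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if rts is None:
        rts = [3.0 + 0.5 * j for j in range(p)]
    if mzs is None:
        mzs = [200.0 + 10.0 * j for j in range(p)]
    if strain_ids is None:
        strain_ids = [f"S{i+1}" for i in range(n)]
    feats = [FeatureKey(rt=r, mz=m) for r, m in zip(rts, mzs)]
    return BucketTable(strain_ids=list(strain_ids), features=feats, values=values)


@pytest.fixture
def small_table():
    """3 strains x 4 features; feature 1 unique to S1, feature 3 unique to S3."""
    return make_table(
        [
            [5.0, 100.0, 2.0, 0.0],
            [5.0, 0.0, 2.0, 0.0],
            [5.0, 0.0, 2.0, 50.0],
        ]
    )
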