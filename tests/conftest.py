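import itertools

import numpy as np
import pytest

from cpmult.datamodel import default_bottleneck_meta, load_fixture_jregion


@pytest.fixture(scope="session")
def jdata():
    """Packaged J-region dataset without bottleneck metadata."""
    return load_fixture_jregion()


@pytest.fixture(scope="session")
def jdata_meta(jdata):
    """J-region dataset with the documented default metadata (s=1e6, f=1e-5)."""
    return jdata.with_meta(
        default_bottleneck_meta(jdata.table("MT-MC").samples))


def compositions(n, k):
    """All k-vectors of non-negative integers summing to n."""
    for cuts in itertools.combinations(range(n + k - 1), k - 1):
        prev = -1
        out = []
        for c in cuts:
            out.append(c - prev - 1)
            prev = c
        out.append(n + k - 2 - prev)
        yield np.array(out, dtype=np.int64)
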