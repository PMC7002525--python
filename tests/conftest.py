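import numpy as np
import pandas as pd
import pytest

from svccf import CNAnnotation, CNState, SampleMeta


@pytest.fixture
def meta():
    return SampleMeta(purity=0.75, ploidy=2.0, error_rate=1e-3,
                      expected_depth=100.0)


@pytest.fixture
def diploid():
    return CNAnnotation((CNState(1, 1, 1.0),))


@pytest.fixture
def subclonal_cn():
    return CNAnnotation((CNState(2, 1, 0.7), CNState(1, 1, 0.3)))


def make_variant_table(rng, n, phi, w, depth=100, eps=1e-3):
    """Draw a (b1,d1,b2,d2) table from the binomial forward model."""
    f = w * phi + eps
    d1 = rng.poisson(depth, n).clip(min=1)
    d2 = rng.poisson(depth, n).clip(min=1)
    return pd.DataFrame({
        "id": [f"v{i}" for i in range(n)],
        "b1": rng.binomial(d1, f), "d1": d1,
        "b2": rng.binomial(d2, f), "d2": d2,
    })
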