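import numpy as np
import pytest

from seqmrf.models import LambdaParameters, lambda_zeros


def random_anchored_lambda(structures, C=None, rng=None, scale=0.8,
                           class_scale=0.4) -> LambdaParameters:
    """Random natural parameters with anchors held at exactly zero."""
    rng = rng if rng is not None else np.random.default_rng(0)
    lam = lambda_zeros(structures, C)
    for c, fi in enumerate(lam.feature_indices):
        v = rng.normal(scale=scale, size=fi.n_features)
        v[fi.anchor_indices()] = 0.0
        lam.values[c] = v
    cv = rng.normal(scale=class_scale, size=lam.C)
    cv[-1] = 0.0
    lam.class_values = cv
    return lam


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
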