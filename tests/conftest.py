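import numpy as np
import pytest

from spikemaxent import PairwiseModel


def random_pairwise(n, seed=0, j_scale=0.2, h_loc=-0.5, h_scale=0.4,
                    j_dist="normal"):
    """A random pairwise model with symmetric zero-diagonal couplings."""
    rng = np.random.default_rng(seed)
    h = rng.normal(h_loc, h_scale, n)
    iu = np.triu_indices(n, k=1)
    J = np.zeros((n, n))
    if j_dist == "normal":
        J[iu] = rng.normal(0.0, j_scale, iu[0].size)
    else:
        J[iu] = rng.uniform(-j_scale, j_scale, iu[0].size)
    J = J + J.T
    return PairwiseModel(h, J)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
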