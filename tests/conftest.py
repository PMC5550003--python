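import itertools

import numpy as np
import pytest

from dwt.counts import PairCountTensor


def random_symmetric_logR(rng, l, low=-20.0, high=20.0):
    A = rng.uniform(low, high, (l, l))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0.0)
    return A


def all_sequences(l):
    """All 4^l length-l code rows."""
    return np.array(list(itertools.product(range(4), repeat=l)),
                    dtype=np.int8)


def random_site_tensor(rng, l, n=50):
    """Pair counts of n sites drawn from random independent column
    distributions (marginally consistent by construction)."""
    probs = rng.dirichlet(np.ones(4), size=l)
    codes = np.stack(
        [rng.choice(4, size=n, p=probs[i]) for i in range(l)], axis=1
    ).astype(np.int8)
    return PairCountTensor.from_sites(codes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
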