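import numpy as np
import pytest
from scipy.special import expit


def make_zinb_counts(n, rng, g0=0.5, g1=-2.0, a0=-7.0, a1=-2.0, phi=2.0,
                     with_offset=True):
    """One taxon's ZINB counts with the study's depth-offset structure."""
    T = (rng.random(n) < 0.5).astype(np.int64)
    off = rng.uniform(7.1, 10.5, n) if with_offset else np.zeros(n)
    pi = expit(g0 + g1 * T)
    lam = np.exp(off + a0 + a1 * T)
    y = rng.poisson(rng.gamma(phi, lam / phi))
    y[rng.random(n) < pi] = 0
    return y, T, off


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def zinb_taxon(rng):
    """(counts, treatment, offset) for a single well-identified taxon."""
    return make_zinb_counts(500, rng)
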