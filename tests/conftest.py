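import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_orthonormal(rng, rows, cols):
    """Deterministic orthonormal-column matrix from a seeded draw."""
    q, r = np.linalg.qr(rng.standard_normal((rows, cols)))
    return q * np.sign(np.diagonal(r))
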