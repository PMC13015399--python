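import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_2x2_params(rng, n):
    """Random (pi0, pi1, mu, X0, X1) draws with X0 >= X1 > 0."""
    out = []
    for _ in range(n):
        pi0, pi1, mu = rng.uniform(0.02, 0.98, size=3)
        X1 = rng.uniform(0.01, 0.1)
        X0 = X1 + rng.uniform(0.005, 0.1)
        out.append((pi0, pi1, mu, X0, X1))
    return out
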