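import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_hmm():
    """A 2-state, 2-component, 3-dimensional model with distinct emissions."""
    from sdhmm import HMMParams

    return HMMParams(
        pi=np.array([0.6, 0.4]),
        B=np.array([[0.8, 0.2], [0.3, 0.7]]),
        C=np.array([[0.7, 0.3], [0.4, 0.6]]),
        alpha=np.array(
            [[[5.0, 1.0, 1.0], [1.0, 5.0, 1.0]], [[1.0, 1.0, 5.0], [2.0, 2.0, 2.0]]]
        ),
        beta=np.array(
            [[[1 / 3, 1 / 3, 1 / 3], [0.2, 0.3, 0.5]], [[0.5, 0.3, 0.2], [1 / 3, 1 / 3, 1 / 3]]]
        ),
    )


def random_hmm(rng, K, M, D):
    from sdhmm import HMMParams

    return HMMParams(
        pi=rng.dirichlet(np.ones(K)),
        B=rng.dirichlet(np.ones(K), size=K),
        C=rng.dirichlet(np.ones(M), size=K),
        alpha=rng.uniform(0.5, 6.0, size=(K, M, D)),
        beta=rng.dirichlet(np.ones(D), size=(K, M)),
    )
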