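import numpy as np
import pytest

from modparc import synthetic as sy


@pytest.fixture(scope="session")
def tiny_spec():
    """Two-subject, short-run phantom for fast structural tests."""
    return sy.default_spec(n_subjects=2, n_runs=2, n_frames=104, seed=42)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    return sy.make_resting_dataset(tiny_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_signed_graph(rng, n, neg_frac=0.3, scale=1.0):
    """Random symmetric signed weight matrix with zero diagonal."""
    from modparc.core import SignedGraph

    w = rng.normal(0.2, scale, size=(n, n))
    sign_flip = rng.random((n, n)) < neg_frac
    w[sign_flip] = -np.abs(w[sign_flip])
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    if np.maximum(w, 0).sum() == 0:  # ensure a positive layer exists
        w[0, 1] = w[1, 0] = 1.0
    return SignedGraph(w)
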