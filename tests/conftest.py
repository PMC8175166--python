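import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_labeled_matrices(rng, n_per_class=(4, 5), c=5, t=8):
    """Small random 2-D trial set with labels 1..p."""
    trials, labels = [], []
    for j, n_j in enumerate(n_per_class, start=1):
        base = rng.standard_normal((c, t))
        for _ in range(n_j):
            trials.append(base + rng.standard_normal((c, t)))
            labels.append(j)
    return np.stack(trials), np.array(labels)


def random_labeled_tensors(rng, n_per_class=(5, 5), shape=(4, 6, 3)):
    """Small random order-h trial set with labels 1..p."""
    trials, labels = [], []
    for j, n_j in enumerate(n_per_class, start=1):
        base = rng.standard_normal(shape)
        for _ in range(n_j):
            trials.append(base + rng.standard_normal(shape))
            labels.append(j)
    return np.stack(trials), np.array(labels)
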