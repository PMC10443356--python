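import numpy as np
import pytest

import sparselogit as sl


def draw_labels(rng, pi):
    """Vectorized categorical draws, one label per row of pi."""
    u = rng.random(pi.shape[0])
    return (u[:, None] > np.cumsum(pi, axis=1)).sum(axis=1)


@pytest.fixture(scope="session")
def j3_dataset():
    """Moderate-signal J=3 dataset with no separation; m = n distinct rows."""
    rng = np.random.default_rng(101)
    n, d = 300, 2
    X = rng.lognormal(0.0, 0.5, (n, d))
    eta = np.stack([0.5 + X @ [0.9, -0.6], -0.1 + X @ [0.2, 0.4]], axis=1)
    pi = sl.probs_from_eta("baseline_category", eta)
    y = draw_labels(rng, pi)
    return X, y


@pytest.fixture(scope="session")
def j4_dataset():
    """J=4 dataset used for the order-invariance and reversal-tie checks."""
    rng = np.random.default_rng(202)
    n, d = 240, 2
    X = rng.lognormal(0.0, 0.5, (n, d))
    eta = np.stack(
        [0.5 + X @ [0.8, -0.5], 0.1 + X @ [0.3, 0.2], -0.2 + X @ [-0.4, 0.6]],
        axis=1,
    )
    pi = sl.probs_from_eta("baseline_category", eta)
    y = draw_labels(rng, pi)
    return sl.CategoricalDataset.from_raw(X, y)


@pytest.fixture(scope="session")
def binary_dataset():
    """Fixed 100-sample binary dataset for the link-equivalence checks."""
    from sparselogit.synthetic import gen_dataset, preset

    X, y, _ = gen_dataset(preset("binary_equivalence"))
    return sl.CategoricalDataset.from_raw(X, y)
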