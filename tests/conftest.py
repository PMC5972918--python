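import numpy as np
import pytest

from fldnrs import ExpressionDataset


@pytest.fixture
def line_dataset():
    """Three samples on a line: 0.0, 1.0, 2.5 (one attribute)."""
    return ExpressionDataset(np.array([[0.0], [1.0], [2.5]]), np.array([1, 2, 2]))


@pytest.fixture
def fld_dataset():
    """One attribute, two classes: {0, 2} and {4, 6}."""
    return ExpressionDataset(
        np.array([[0.0], [2.0], [4.0], [6.0]]), np.array([1, 1, 2, 2])
    )


def random_dataset(rng, n_max=30, t_max=5, c_choices=(2, 3)):
    """Small random dataset in [0, 1]^T with every class nonempty."""
    n = int(rng.integers(4, n_max + 1))
    T = int(rng.integers(1, t_max + 1))
    c = int(rng.choice(c_choices))
    labels = np.concatenate([np.arange(c), rng.integers(0, c, n - c)])
    rng.shuffle(labels)
    return ExpressionDataset(rng.random((n, T)), labels)
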