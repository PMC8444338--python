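import numpy as np
import pytest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210827)


def align_signs(Y: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Flip columns of Y so each has non-negative inner product with ref's."""
    Y = Y.copy()
    for k in range(Y.shape[1]):
        if Y[:, k] @ ref[:, k] < 0:
            Y[:, k] = -Y[:, k]
    return Y


def sampled_cosine(n: int, order: int) -> np.ndarray:
    """cos(order * pi * t / n) on the package's t = 1..n sampling grid."""
    t = np.arange(1, n + 1)
    return np.cos(order * np.pi * t / n)


def sampled_sine(n: int, order: int) -> np.ndarray:
    t = np.arange(1, n + 1)
    return np.sin(order * np.pi * t / n)
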