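import numpy as np
import pytest

from erpspeller import cnn
from erpspeller.montage import N_INPUT_ROWS, N_SAMPLES


def tiny_spec(**overrides) -> cnn.CnnSpec:
    """Small, fast network spec for unit tests (same architecture family)."""
    defaults = dict(l1_filters=2, l2_filters=2, f1_units=8, iterations=120,
                    batch_size=16, record_every=60, seed=3)
    defaults.update(overrides)
    return cnn.CnnSpec(**defaults)


def separable_inputs(n_pos: int = 24, n_neg: int = 48, noise: float = 0.3,
                     bump_amp: float = 5.0, seed: int = 0):
    """Wrapped input matrices with a clearly separable parietal bump for
    positives; a linear classifier already achieves 100% on these."""
    rng = np.random.default_rng(seed)
    t = np.arange(N_SAMPLES) / 256.0
    bump = bump_amp * np.exp(-0.5 * ((t - 0.5) / 0.05) ** 2)
    x = noise * rng.standard_normal((n_pos + n_neg, N_INPUT_ROWS, N_SAMPLES))
    x[:n_pos, 6:9, :] += bump
    y = np.zeros(n_pos + n_neg, dtype=bool)
    y[:n_pos] = True
    return x.astype(np.float32), y


@pytest.fixture(scope="session")
def tiny_model():
    """A quickly trained small CNN on separable data, shared across tests."""
    x, y = separable_inputs()
    return cnn.train(tiny_spec(), x, y)
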