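import numpy as np
import pytest

from rangeff import AtomicConfiguration, EnergyModel, ModelConfig
from rangeff.baseline_mpnn import BaselineHyperparams
from rangeff.range_layer import RangeHyperparams


def tiny_model_config(range_enabled=True, K=2, H=2, F=16, T=2, n_pe=8,
                      cutoff=5.0, n_rbf=8):
    return ModelConfig(
        baseline=BaselineHyperparams(F=F, T=T, cutoff=cutoff, n_rbf=n_rbf),
        range_hp=RangeHyperparams(n_masters=K, n_heads=H, head_dim=F // H, n_pe=n_pe),
        range_enabled=range_enabled,
    )


@pytest.fixture
def tiny_model():
    return EnergyModel(tiny_model_config(), seed=0)


@pytest.fixture
def random_config():
    rng = np.random.default_rng(42)
    return AtomicConfiguration(
        positions=rng.uniform(0.0, 7.0, (12, 3)),
        species=rng.integers(1, 12, 12),
    )


def random_rotation(rng):
    u = rng.normal(size=4)
    w, x, y, z = u / np.linalg.norm(u)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
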