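import numpy as np
import pytest
import scipy.linalg

from popgex import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def sim_small():
    """400-gene simulated dataset with ground truth (fixed seed)."""
    cfg = SimulationConfig(n_genes=400, seed=7)
    matrix, truth = simulate_dataset(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def sim_default():
    """Full-size default simulation: 4000 genes, 18 samples, 30-min period."""
    cfg = SimulationConfig(seed=11)
    matrix, truth = simulate_dataset(cfg)
    return cfg, matrix, truth


def planted_linear_system(n_genes=60, rank=4, omega=2 * np.pi / 30, tau=7.0,
                          n_times=18, seed=0):
    """Noiseless data X = W exp(B tau k) v0 with a planted rotation block.

    B has one 2x2 rotation block (frequency omega) and real decay rates on
    the remaining diagonal.  Returns (X, times, W, B, v0).
    """
    rng = np.random.default_rng(seed)
    b = np.zeros((rank, rank))
    b[0, 1] = -omega
    b[1, 0] = omega
    for i in range(2, rank):
        b[i, i] = -0.01 * (i - 1)
    w = rng.normal(size=(n_genes, rank))
    v0 = rng.normal(size=rank)
    times = np.arange(n_times) * tau
    v = np.column_stack([scipy.linalg.expm(b * t) @ v0 for t in times])
    return w @ v, times, w, b, v0
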