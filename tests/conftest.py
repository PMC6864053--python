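import numpy as np
import pytest

from tmstensor.cpd import khatri_rao
from tmstensor.synthdata import SimConfig, make_ground_truth, synth_tensor5d


SMALL = dict(n_channels=16, n_freqs=12, n_times=20, n_subjects=8, n_conditions=4)


@pytest.fixture(scope="session")
def small_config():
    """Reduced-size study configuration (same structure, desk-scale modes)."""
    return SimConfig(seed=7, noise_level=0.05, **SMALL)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return make_ground_truth(small_config)


@pytest.fixture(scope="session")
def small_tensor(small_truth, small_config):
    return synth_tensor5d(small_truth, small_config)


@pytest.fixture(scope="session")
def noiseless_setup():
    """Noiseless, full-column-rank rank-3 construction (condition jitter on)."""
    cfg = SimConfig(seed=7, noise_level=0.0, condition_jitter=0.15, **SMALL)
    gt = make_ground_truth(cfg)
    return cfg, gt, synth_tensor5d(gt, cfg)


def random_cp_tensor(shape, rank, seed, noise=0.0):
    """Generic non-negative rank-R tensor with well-conditioned factors."""
    rng = np.random.default_rng(seed)
    factors = [np.abs(rng.standard_normal((s, rank))) for s in shape]
    signal = (khatri_rao(factors) @ np.ones(rank)).reshape(shape)
    if noise > 0:
        signal = signal + noise * np.sqrt((signal**2).mean()) * rng.standard_normal(shape)
    return signal, factors
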