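import numpy as np
import pytest

from erpica.ica import fit_infomax
from erpica.pipeline import RunConfig, run_pipeline
from erpica.synth import (
    SimConfig,
    make_ground_truth,
    recovery_config,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def quiet_config():
    """No noise, no jitter, no group effect: exact algebra everywhere."""
    return SimConfig(n_per_group=4, seed=11)


@pytest.fixture(scope="session")
def quiet_dataset(quiet_config):
    gt = make_ground_truth(quiet_config, 7)
    return gt, simulate_dataset(gt, quiet_config)


@pytest.fixture(scope="session")
def toy_mixture():
    """Two Laplacian sources through a fixed 2x2 mixing matrix."""
    rng = np.random.default_rng(7)
    S = rng.laplace(size=(2, 5000))
    A = np.array([[1.0, 0.6], [-0.4, 1.0]])
    return A, S, A @ S


@pytest.fixture(scope="session")
def toy_model(toy_mixture):
    _, _, P = toy_mixture
    return fit_infomax(P, seed=3)


@pytest.fixture(scope="session")
def square_model():
    """Full-rank 4-channel fit (no average reference), so the filters
    must sum to the identity exactly."""
    rng = np.random.default_rng(21)
    S = rng.laplace(size=(4, 6000))
    A = rng.standard_normal((4, 4)) + 2 * np.eye(4)
    return fit_infomax(A @ S, seed=5), A @ S


@pytest.fixture(scope="session")
def recovery_dataset():
    """Noiseless 7-source cohort with realistic between-subject
    variability; the decomposition-recovery benchmark."""
    cfg = recovery_config(seed=3)
    gt = make_ground_truth(cfg, 7)
    return cfg, gt, simulate_dataset(gt, cfg)


@pytest.fixture(scope="session")
def benchmark_result():
    """The packaged 74+74 benchmark, run once for the whole session."""
    cfg = RunConfig()
    return cfg, run_pipeline(cfg)
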