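import numpy as np
import pytest

from fallwatch import FallDetector, FitConfig, simulate_cohort
from fallwatch.svi_gmm import DIM, PriorSpec, VariationalState, _softplus_inv


def make_cluster_data(rng, n, means, covs, weights):
    """Draw n points from a known 2-D Gaussian mixture (the recovery truth)."""
    means = np.asarray(means, dtype=float)
    covs = np.asarray(covs, dtype=float)
    weights = np.asarray(weights, dtype=float)
    z = rng.choice(len(weights), size=n, p=weights)
    X = np.empty((n, 2))
    for k in range(len(weights)):
        idx = z == k
        X[idx] = rng.multivariate_normal(means[k], covs[k], size=int(idx.sum()))
    return X, z


WELL_SEPARATED = dict(
    means=[[0.0, 0.0], [2.5, 0.5], [-1.5, 2.0]],
    covs=[
        [[0.08, 0.02], [0.02, 0.05]],
        [[0.06, -0.03], [-0.03, 0.09]],
        [[0.05, 0.0], [0.0, 0.05]],
    ],
    weights=[0.5, 0.3, 0.2],
)

CORRELATED = dict(
    means=[[0.0, 0.0], [2.2, 0.8], [-1.6, 2.0]],
    covs=[
        [[0.20, 0.16], [0.16, 0.20]],
        [[0.25, 0.20], [0.20, 0.25]],
        [[0.18, 0.144], [0.144, 0.18]],
    ],
    weights=[0.4, 0.35, 0.25],
)


def random_state(rng, K=3, mode="full"):
    """A random valid variational state (finite raw parameters)."""
    raw = {
        "n1": rng.normal(0, 1.5, (K, DIM)),
        "log_n2": rng.normal(-1.0, 0.5, (K, DIM)),
        "w1_raw": rng.normal(0.7, 0.5, K),
        "lw_log_diag": rng.normal(0.0, 0.5, (K, DIM)),
        "d_raw": _softplus_inv(rng.uniform(0.3, 4.0, K)),
        "gate_weights": np.zeros((4, 4)),
        "gate_bias": np.zeros(4),
        "projection": np.zeros((4, 2)),
    }
    if mode == "full":
        raw["lw_off"] = rng.normal(0, 0.5, K)
    return VariationalState(K=K, covariance_mode=mode, raw=raw)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def fall_cohort():
    return simulate_cohort(15, seed=11)


@pytest.fixture(scope="session")
def fall_detector(fall_cohort):
    """Detector trained at default settings on the first 10 subjects."""
    return FallDetector.train(fall_cohort[:20], FitConfig(K=3), seed=3)
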