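import numpy as np
import pytest

from teflow.synthetic import CouplingSpec, SyntheticDesign, generate_recording


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260917)


@pytest.fixture(scope="session")
def two_channel_coupled():
    """A 2-channel design with one EM-only coupling A->B at delay 5."""
    return SyntheticDesign(
        n_channels=2,
        channel_labels=("A", "B"),
        rate=100,
        duration_samples=2000,
        ar_coeff=0.5,
        noise_sd=1.0,
        couplings=(CouplingSpec("A", "B", delay=5, strength=0.5,
                                conditions=frozenset({"EM"})),),
        seed=11,
    )


@pytest.fixture(scope="session")
def coupled_recording(two_channel_coupled):
    return generate_recording(two_channel_coupled, "S00", "EM")


def standard_var(coupling: float = 0.5):
    """Coefficients/noise of the reference bivariate VAR(1) used throughout:
    x_t = 0.5 x_{t-1} + e_t,  y_t = 0.5 y_{t-1} + c x_{t-1} + n_t."""
    return np.array([[0.5, 0.0], [coupling, 0.5]]), np.eye(2)


def simulate_var(A, n, seed, burn=200):
    rng = np.random.default_rng(seed)
    d = A.shape[0]
    out = np.zeros((d, n + burn))
    eps = rng.standard_normal((d, n + burn))
    for t in range(1, n + burn):
        out[:, t] = A @ out[:, t - 1] + eps[:, t]
    return out[:, burn:]
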