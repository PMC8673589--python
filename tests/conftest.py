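import numpy as np
import pytest

from denoiseiq import phantom_imaging as pi


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def tiny_study32():
    """Scaled-down 32x32 study used by unit tests."""
    return pi.study_32(n_train=200, n_validation=40, n_test=400,
                       n_observer_calibration=200, n_covariance=400)


@pytest.fixture(scope="session")
def tiny_system():
    return pi.CollimatorSystem(shape=(16, 16), height=20.0, psf_width=2.0)


@pytest.fixture(scope="session")
def gaussian_toy():
    """Small equal-covariance Gaussian two-class problem with known statistics.

    Correlated 5x5 'images' where the Hotelling observer is the ideal
    observer and its AUC has the closed form Phi(d/sqrt(2)).
    """
    rng = np.random.default_rng(7)
    p = 25
    a = rng.normal(size=(p, p))
    cov = a @ a.T / p + 0.5 * np.eye(p)
    delta = rng.normal(scale=0.35, size=p)
    chol = np.linalg.cholesky(cov)
    n = 4000
    g0 = (rng.normal(size=(n, p)) @ chol.T).reshape(n, 5, 5)
    g1 = (rng.normal(size=(n, p)) @ chol.T + delta).reshape(n, 5, 5)
    d2 = float(delta @ np.linalg.solve(cov, delta))
    return {"g0": g0, "g1": g1, "cov": cov, "delta": delta, "d": np.sqrt(d2)}
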