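import numpy as np
import pytest
import scipy.linalg

from grmscan import PhenoCov, SimConfig, simulate_dataset


def random_pd(rng: np.random.Generator, n: int, jitter: float = 1.0) -> np.ndarray:
    """A well-conditioned random positive-definite matrix."""
    A = rng.normal(size=(n, n))
    return A @ A.T + jitter * n * np.eye(n)


def phenocov_from_matrix(V, sigma_g2=1.0, sigma_e2=1.0, scale_c=1.0) -> PhenoCov:
    """Wrap an arbitrary PD matrix as a phenotypic covariance."""
    V = np.asarray(V, dtype=float)
    Vinv = scipy.linalg.inv(V)
    return PhenoCov(V, 0.5 * (Vinv + Vinv.T), sigma_g2, sigma_e2, scale_c)


@pytest.fixture(scope="session")
def small_dataset():
    """A seeded stratified panel: raw/centered genotypes, GRM, phenotype."""
    cfg = SimConfig(n=40, p=150, n_subpops=2, divergence=0.3, h2_true=0.5, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def medium_dataset():
    """Larger panel for variance-component and scan behavior checks."""
    cfg = SimConfig(n=120, p=600, n_subpops=2, divergence=0.3, h2_true=0.5, seed=7)
    return simulate_dataset(cfg)
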