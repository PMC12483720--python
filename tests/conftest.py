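import numpy as np
import pytest

from bifactor import (
    ALMConfig,
    BiFactorParams,
    GroupCorrelationParams,
    LoadingMatrix,
    SampleCovariance,
    SimulationDesign,
    Uniquenesses,
    generate_exact_model,
    model_covariance,
    population_input,
)
from bifactor.core import n_free_beta


def random_params(rng: np.random.Generator, J: int, G: int) -> BiFactorParams:
    """Generic random parameter triplet for oracle checks."""
    return BiFactorParams(
        LoadingMatrix(rng.normal(scale=0.7, size=(J, G + 1))),
        GroupCorrelationParams(rng.normal(scale=0.5, size=n_free_beta(G))),
        Uniquenesses(rng.uniform(0.5, 1.5, size=J)),
    )


def random_sample(rng: np.random.Generator, J: int, N: int = 200) -> SampleCovariance:
    """Well-conditioned random PD sample covariance."""
    A = rng.normal(size=(J, J + 3))
    S = A @ A.T / (J + 3) + 0.5 * np.eye(J)
    return SampleCovariance(S=S, N=N)


@pytest.fixture(scope="session")
def small_truth():
    """Exact bi-factor population: J=15, G=3, clusters of five."""
    return generate_exact_model(SimulationDesign(J=15, G=3, N=500, seed=7))


@pytest.fixture(scope="session")
def small_population(small_truth):
    return population_input(small_truth, N=500)


@pytest.fixture(scope="session")
def fast_config():
    return ALMConfig.profile("simulation", n_starts=5, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_fit(small_population, fast_config):
    """One converged multistart fit on the population covariance (shared)."""
    from bifactor import fit_multistart

    return fit_multistart(small_population, 3, fast_config)


def exact_sigma_sample(params: BiFactorParams, N: int = 500) -> SampleCovariance:
    return SampleCovariance(S=model_covariance(params), N=N)
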