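"""Synthetic bi-factor models and data: the simulation engine.

Two data-generating mechanisms are provided:

* an **exact** bi-factor model -- each variable loads on the general factor
  and exactly one group factor, with loading magnitudes drawn uniformly and
  signs drawn from a Bernoulli distribution;
* an **approximate** bi-factor model -- the exact loading matrix plus small
  uniform perturbations on the off-cluster group loadings, so the truth
  violates the bi-factor constraints while staying close to them.

Group-factor correlations come from uniform draws of the unconstrained
Cholesky parameters, and all uniquenesses share one value.  Data are i.i.d.
mean-zero multivariate normal draws from the implied covariance.

Defaults define the package's study conditions: loading magnitudes U(0.5, 1.5)
with sign +1 w.p. 0.5, perturbations U(0, 0.1), beta U(-1, 1), psi = 1, and
contiguous equal-block clusters.  The two reference designs are a small one
(J=15, G=3, blocks of 5) and a large one (J=30, G=5, blocks of 6) with sample
sizes N in {500, 20000}; the large design at N=500 is the hardest setting.
A simulation study fixes the model seed (one draw of Lambda0, Phi0) and varies
only the data seed across replications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constraints import bifactor_distance
from .core import (
    BiFactorParams,
    GroupCorrelationParams,
    LoadingMatrix,
    SampleCovariance,
    Uniquenesses,
    model_covariance,
    n_free_beta,
)
from .structure import BiFactorStructure

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "generate_exact_model",
    "generate_approx_model",
    "sample_dataset",
    "population_input",
    "study_designs",
]


@dataclass
class SimulationDesign:
    """Complete recipe for one simulated bi-factor population and its data."""

    J: int
    G: int
    N: int
    clusters: str | list[list[int]] = "equal_blocks"
    general_range: tuple[float, float] = (0.5, 1.5)
    group_range: tuple[float, float] = (0.5, 1.5)
    sign_prob: float = 0.5
    perturb_range: tuple[float, float] = (0.0, 0.1)
    beta_range: tuple[float, float] = (-1.0, 1.0)
    psi_value: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.J < 1 or self.G < 1 or self.N < 1:
            raise ValueError("J, G and N must be positive")
        for name in ("general_range", "group_range", "perturb_range", "beta_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} must be ordered (low, high)")
        if not 0 <= self.sign_prob <= 1:
            raise ValueError("sign_prob must lie in [0, 1]")
        if self.psi_value <= 0:
            raise ValueError("psi_value must be positive")
        if self.clusters == "equal_blocks" and self.J % self.G != 0:
            raise ValueError(
                f"equal_blocks requires J divisible by G; got J={self.J}, G={self.G}"
            )

    def cluster_sets(self) -> list[frozenset[int]]:
        """Resolve the cluster specification into 1-based variable sets."""
        if self.clusters == "equal_blocks":
            size = self.J // self.G
            return [
                frozenset(range(g * size + 1, (g + 1) * size + 1))
                for g in range(self.G)
            ]
        sets = [frozenset(c) for c in self.clusters]
        structure = BiFactorStructure(clusters=sets, J=self.J)  # validates
        if structure.unassigned:
            raise ValueError(
                f"cluster specification leaves variables unassigned: "
                f"{sorted(structure.unassigned)}"
            )
        return sets


@dataclass
class GroundTruth:
    """True parameters, structure and population covariance of a design."""

    params: BiFactorParams
    structure: BiFactorStructure
    population_cov: np.ndarray
    is_exact: bool
    design: SimulationDesign | None = field(default=None, repr=False)


def _draw_model(design: SimulationDesign, exact: bool) -> GroundTruth:
    rng = np.random.default_rng(design.seed)
    clusters = design.cluster_sets()
    J, G = design.J, design.G
    lam = np.zeros((J, G + 1))
    lam[:, 0] = rng.uniform(*design.general_range, size=J)
    signs = np.where(rng.random(J) < design.sign_prob, 1.0, -1.0)
    membership = {j: g for g, cl in enumerate(clusters, start=1) for j in cl}
    for j in range(1, J + 1):
        g = membership[j]
        lam[j - 1, g] = signs[j - 1] * rng.uniform(*design.group_range)
    if not exact:
        off = np.ones((J, G), dtype=bool)
        for j in range(1, J + 1):
            off[j - 1, membership[j] - 1] = False
        mags = rng.uniform(*design.perturb_range, size=(J, G))
        pert_signs = np.where(rng.random((J, G)) < 0.5, 1.0, -1.0)
        lam[:, 1:][off] = (mags * pert_signs)[off]
    beta = rng.uniform(*design.beta_range, size=n_free_beta(G))
    params = BiFactorParams(
        LoadingMatrix(lam),
        GroupCorrelationParams(beta),
        Uniquenesses(np.full(J, design.psi_value)),
    )
    structure = BiFactorStructure(clusters=clusters, J=J)
    is_exact = bifactor_distance(lam) == 0.0
    return GroundTruth(
        params=params,
        structure=structure,
        population_cov=model_covariance(params),
        is_exact=is_exact,
        design=design,
    )


def generate_exact_model(design: SimulationDesign) -> GroundTruth:
    """Draw a seeded exact bi-factor population (zero off-cluster loadings)."""
    return _draw_model(design, exact=True)


def generate_approx_model(design: SimulationDesign) -> GroundTruth:
    """Draw a seeded approximate bi-factor population.

    Off-cluster group loadings receive i.i.d. perturbations with magnitude
    uniform on ``perturb_range`` and random sign; a zero-width range
    degenerates to the exact model.
    """
    return _draw_model(design, exact=False)


def sample_dataset(
    truth: GroundTruth,
    N: int,
    seed: int,
    denominator: str = "ml",
) -> tuple[np.ndarray, SampleCovariance]:
    """Draw N i.i.d. mean-zero normal observations from the population
    covariance and form their sample covariance."""
    if N < truth.structure.J:
        import warnings

        warnings.warn(
            f"N={N} below J={truth.structure.J}: sample covariance is singular",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(truth.population_cov)
    X = rng.standard_normal((N, truth.structure.J)) @ chol.T
    return X, SampleCovariance.from_data(X, denominator=denominator)


def population_input(truth: GroundTruth, N: int = 10_000) -> SampleCovariance:
    """Wrap the population covariance itself as the solver input.

    ``N`` only enters BIC-type formulas downstream; the matrix is exact, so a
    fit against it probes population-level (identifiability) recovery.
    """
    return SampleCovariance(S=truth.population_cov.copy(), N=N)


def study_designs(setting: str = "exact") -> dict[str, SimulationDesign]:
    """The package's reference simulation grid.

    Four cells: {small, large} design x N in {500, 20000}, with the small
    design J=15, G=3 and the large design J=30, G=5.  ``setting`` picks the
    exact or approximate truth; keys look like ``'J30_G5_N500'``.  The sample
    sizes straddle the BIC-consistency threshold of the unrestricted-EFA
    baseline, which separates the regimes where ignoring the bi-factor
    structure does and does not recover the factor count.
    """
    if setting not in ("exact", "approx"):
        raise ValueError("setting must be 'exact' or 'approx'")
    perturb = (0.0, 0.0) if setting == "exact" else (0.0, 0.1)
    grid = {}
    for J, G in ((15, 3), (30, 5)):
        for N in (500, 20000):
            grid[f"J{J}_G{G}_N{N}"] = SimulationDesign(
                J=J, G=G, N=N, perturb_range=perturb
            )
    return grid
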