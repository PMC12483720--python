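"""Bi-factor equality constraints, feasibility distance, and structure extraction.

A loading matrix has an exact bi-factor structure when every row of its group
block contains at most one nonzero entry.  That combinatorial statement is
encoded as smooth equality constraints: products of distinct group loadings in
the same row must vanish.  Two algebraic forms are available:

``pairwise``
    residuals c_{j,g,g'} = lambda_{jg} * lambda_{jg'} for every row j and every
    pair g < g' (J*G(G-1)/2 constraints) -- bilinear, the default;
``row_aggregate``
    one quartic residual per row, c_j = sum_{g<g'} lambda_{jg}^2 lambda_{jg'}^2.

Both vanish exactly on the bi-factor set.  The distance from the bi-factor
set used in the stopping rule is the largest second-largest absolute group
loading across rows: it is zero iff the structure is exact, and being below a
threshold eps means each row has at most one group loading above eps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import BiFactorParams, LoadingMatrix, build_phi
from .structure import BiFactorStructure

__all__ = [
    "ToleranceConfig",
    "ConstraintVector",
    "constraint_values",
    "n_constraints",
    "second_largest",
    "bifactor_distance",
    "extract_structure",
    "parameter_change",
]

CONSTRAINT_FORMS = ("pairwise", "row_aggregate")


@dataclass
class ToleranceConfig:
    """Stopping thresholds: eps_param for parameter change, eps_struct for the
    distance to the bi-factor set."""

    eps_param: float = 1e-4
    eps_struct: float = 1e-3

    def __post_init__(self) -> None:
        if self.eps_param <= 0 or self.eps_struct <= 0:
            raise ValueError("tolerances must be strictly positive")


@dataclass
class ConstraintVector:
    values: np.ndarray
    form: str

    @property
    def max_abs(self) -> float:
        return float(np.max(np.abs(self.values))) if self.values.size else 0.0


def n_constraints(J: int, G: int, form: str = "pairwise") -> int:
    if form == "pairwise":
        return J * G * (G - 1) // 2
    if form == "row_aggregate":
        return J if G > 1 else 0
    raise ValueError(f"unknown constraint form {form!r}; choose from {CONSTRAINT_FORMS}")


def _group_block(loadings) -> np.ndarray:
    if isinstance(loadings, LoadingMatrix):
        return loadings.group
    arr = np.asarray(loadings, dtype=float)
    return arr[:, 1:]


def constraint_values(loadings, form: str = "pairwise") -> ConstraintVector:
    """Evaluate the equality-constraint residuals on a loading matrix.

    Returns the zero vector iff the group block has an exact bi-factor
    structure.  With G = 1 the constraint set is empty.
    """
    B = _group_block(loadings)
    G = B.shape[1]
    if form not in CONSTRAINT_FORMS:
        raise ValueError(
            f"unknown constraint form {form!r}; choose from {CONSTRAINT_FORMS}"
        )
    if G < 2:
        return ConstraintVector(np.empty(0), form)
    iu, ju = np.triu_indices(G, k=1)
    pair_products = B[:, iu] * B[:, ju]  # J x G(G-1)/2
    if form == "pairwise":
        return ConstraintVector(pair_products.ravel(), form)
    return ConstraintVector(np.sum(pair_products**2, axis=1), form)


def second_largest(v: np.ndarray) -> float:
    """Second-largest entry of a vector; 0 for vectors of length < 2.

    Duplicated maxima count separately, so second_largest((a, a)) = a.  The
    length-1 convention makes single-group models automatically feasible.
    """
    v = np.atleast_1d(np.asarray(v, dtype=float))
    if v.size < 2:
        return 0.0
    return float(np.partition(v, -2)[-2])


def bifactor_distance(loadings) -> float:
    """Distance from the set of exact bi-factor loading matrices.

    max over rows j of the second-largest |group loading| in row j; zero iff
    every row has at most one nonzero group loading.
    """
    B = np.abs(_group_block(loadings))
    if B.shape[1] < 2 or B.shape[0] == 0:
        return 0.0
    part = np.partition(B, B.shape[1] - 2, axis=1)[:, B.shape[1] - 2]
    return float(np.max(part))


def extract_structure(loadings, eps_struct: float) -> BiFactorStructure:
    """Read the estimated bi-factor structure off a (near-)feasible solution.

    Variable j is assigned to group g when |lambda_{jg}| > eps_struct.  When
    the distance to the bi-factor set is below eps_struct this rule assigns
    each variable to at most one group; rows whose group loadings are all
    below the threshold load on the general factor only and are reported
    unassigned.
    """
    B = _group_block(loadings)
    J, G = B.shape
    dist = bifactor_distance(loadings)
    if dist >= eps_struct:
        warnings.warn(
            f"extracting structure from a solution at distance {dist:.3e} >= "
            f"eps_struct={eps_struct:.1e} from the bi-factor set; ties broken "
            "by largest absolute loading",
            stacklevel=2,
        )
    clusters: list[set[int]] = [set() for _ in range(G)]
    absB = np.abs(B)
    for j in range(J):
        above = np.flatnonzero(absB[j] > eps_struct)
        if above.size == 0:
            continue
        if above.size == 1:
            clusters[above[0]].add(j + 1)
        else:
            # precondition violated: pick the dominant loading, lowest column
            # index on exact ties (warned above)
            g = int(np.argmax(absB[j]))
            clusters[g].add(j + 1)
    return BiFactorStructure(clusters=[frozenset(c) for c in clusters], J=J)


def parameter_change(prev: BiFactorParams, curr: BiFactorParams) -> float:
    """Change between consecutive iterates:

    ||Lambda_t - Lambda_{t-1}||_F + ||Phi_t - Phi_{t-1}||_F
    + ||psi_t - psi_{t-1}||_2  (unnormalized sum of block norms).
    """
    if prev.J != curr.J or prev.G != curr.G:
        raise ValueError("parameter dimensions differ between iterates")
    d_lam = np.linalg.norm(prev.loadings.values - curr.loadings.values)
    d_phi = np.linalg.norm(
        build_phi(prev.corr_params, prev.G) - build_phi(curr.corr_params, curr.G)
    )
    d_psi = np.linalg.norm(prev.uniq.psi - curr.uniq.psi)
    return float(d_lam + d_phi + d_psi)
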