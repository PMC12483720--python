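"""Structure-recovery and estimation-accuracy metrics.

Factor solutions are only identified up to a relabeling P of the group
factors and per-factor sign flips D, so every comparison against a ground
truth first optimizes over those symmetries:

* ``loading_mse`` -- mean squared error of the loading matrix minimized over
  (P, D), computed exactly through sign-optimal per-column costs and an
  optimal assignment;
* ``emc`` -- exact match criterion: 1 iff the estimated clusters equal the
  true clusters up to relabeling;
* ``acc`` -- average correctness criterion: best-permutation proportion of
  correctly classified zero/nonzero group loadings;
* ``selection_correctness`` -- indicator that the selected number of group
  factors equals the truth.

``hard_threshold`` reproduces the post-hoc sparsification used with
rotation-based exploratory bi-factor analysis (which need not return an exact
bi-factor pattern), and ``check_condition3`` verifies the checkable
identifiability condition: every cluster carries at least three nonzero group
loadings and at least three groups have group loadings linearly independent
of the corresponding general-factor loadings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import LoadingMatrix
from .structure import BiFactorStructure

__all__ = [
    "MatchResult",
    "loading_mse",
    "emc",
    "acc",
    "per_factor_correct_count",
    "selection_correctness",
    "hard_threshold",
    "check_condition3",
]


@dataclass
class MatchResult:
    """Value of a permutation-optimized criterion plus the optimizing labels."""

    value: float
    best_permutation: tuple[int, ...]
    per_factor_counts: tuple[int, ...]


def _as_values(loadings) -> np.ndarray:
    if isinstance(loadings, LoadingMatrix):
        return loadings.values
    return np.asarray(loadings, dtype=float)


def loading_mse(true_loadings, est_loadings) -> float:
    """MSE of the estimated loading matrix after resolving (P, D).

    min over group-column permutations P and per-column sign flips D of
    ||Lambda_true - Lambda_est D P||_F^2 / (J (G+1)).  The general column is
    matched to itself with an optimal sign; group columns are matched by an
    optimal assignment over sign-optimal pairwise costs, which is exact
    because the squared norm separates over columns.
    """
    A = _as_values(true_loadings)
    B = _as_values(est_loadings)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: true {A.shape} vs estimate {B.shape}")
    J, K = A.shape
    G = K - 1
    total = min(
        np.sum((A[:, 0] - B[:, 0]) ** 2), np.sum((A[:, 0] + B[:, 0]) ** 2)
    )
    if G > 0:
        At, Bt = A[:, 1:], B[:, 1:]
        # cost[g, a] = min over sign of ||At_g -/+ Bt_a||^2
        cross = At.T @ Bt
        sq = np.sum(At**2, axis=0)[:, None] + np.sum(Bt**2, axis=0)[None, :]
        cost = sq - 2.0 * np.abs(cross)
        rows, cols = linear_sum_assignment(cost)
        total += float(cost[rows, cols].sum())
    return max(float(total), 0.0) / (J * K)


def _check_structures(true_structure: BiFactorStructure, est_structure: BiFactorStructure):
    if true_structure.J != est_structure.J:
        raise ValueError(
            f"structures describe different J: {true_structure.J} vs {est_structure.J}"
        )
    if true_structure.G != est_structure.G:
        warnings.warn(
            f"structures have different numbers of group factors "
            f"({true_structure.G} vs {est_structure.G}); treating as a mismatch",
            stacklevel=3,
        )
        return False
    return True


def per_factor_correct_count(
    true_cluster: frozenset[int] | set[int],
    est_cluster: frozenset[int] | set[int],
    J: int,
) -> int:
    """Correctly identified nonzero plus zero group loadings for one factor:
    |I ∩ Î| + |I^c ∩ Î^c| out of J."""
    I = frozenset(true_cluster)
    E = frozenset(est_cluster)
    universe = frozenset(range(1, J + 1))
    return len(I & E) + len((universe - I) & (universe - E))


def emc(true_structure: BiFactorStructure, est_structure: BiFactorStructure) -> int:
    """Exact match criterion: 1 iff the cluster partitions agree up to a
    relabeling of the group factors (and the same variables are unassigned)."""
    if not _check_structures(true_structure, est_structure):
        return 0
    return int(
        sorted(true_structure.clusters, key=sorted)
        == sorted(est_structure.clusters, key=sorted)
    )


def acc(true_structure: BiFactorStructure, est_structure: BiFactorStructure) -> MatchResult:
    """Average correctness criterion.

    max over permutations sigma of
    (1/(J G)) sum_g [ |I_g ∩ Î_sigma(g)| + |I_g^c ∩ Î_sigma(g)^c| ],
    solved exactly as an optimal assignment on the per-pair counts.
    Variables the estimate leaves unassigned count as all-zero group loadings.
    """
    if not _check_structures(true_structure, est_structure):
        return MatchResult(0.0, (), ())
    J, G = true_structure.J, true_structure.G
    counts = np.empty((G, G))
    for g, I in enumerate(true_structure.clusters):
        for a, E in enumerate(est_structure.clusters):
            counts[g, a] = per_factor_correct_count(I, E, J)
    rows, cols = linear_sum_assignment(-counts)
    perm = tuple(int(c) for c in cols)
    per_factor = tuple(int(counts[g, perm[g]]) for g in range(G))
    return MatchResult(float(sum(per_factor)) / (J * G), perm, per_factor)


def selection_correctness(chosen_G: int, true_G: int) -> int:
    """SC criterion: indicator that the selected G equals the true G."""
    return int(chosen_G == true_G)


def hard_threshold(loadings, tau: float) -> LoadingMatrix:
    """Zero out group loadings with |lambda| < tau (general column untouched).

    The result need not satisfy the bi-factor structure: several group
    loadings in a row may survive the threshold.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    vals = _as_values(loadings).copy()
    grp = vals[:, 1:]
    grp[np.abs(grp) < tau] = 0.0
    return LoadingMatrix(vals)


def check_condition3(truth, tol: float = 1e-8) -> tuple[bool, dict]:
    """Checkable identifiability condition on an exact bi-factor model.

    Requires (i) every cluster to contain at least three variables with
    nonzero group loadings and (ii) at least three groups whose group-loading
    vector is linearly independent of the corresponding general loadings
    (numerical rank 2 of the J_g x 2 matrix [general | group], relative
    tolerance ``tol``).

    ``truth`` may be a GroundTruth-like object with ``params`` and
    ``structure`` attributes, or a tuple ``(loadings, structure)``.
    """
    if hasattr(truth, "params"):
        loadings = truth.params.loadings
        structure = truth.structure
    else:
        loadings, structure = truth
    vals = _as_values(loadings)
    report: dict = {"small_clusters": [], "proportional_groups": [], "independent_groups": []}
    ok_sizes = True
    n_independent = 0
    for g, cluster in enumerate(structure.clusters, start=1):
        idx = np.array(sorted(cluster), dtype=int) - 1
        nonzero = idx[np.abs(vals[idx, g]) > tol] if idx.size else idx
        if nonzero.size < 3:
            ok_sizes = False
            report["small_clusters"].append(g)
            continue
        M = vals[np.ix_(nonzero, [0, g])]
        sv = np.linalg.svd(M, compute_uv=False)
        if sv[-1] > tol * max(1.0, sv[0]):
            n_independent += 1
            report["independent_groups"].append(g)
        else:
            report["proportional_groups"].append(g)
    ok = ok_sizes and n_independent >= 3
    report["n_independent"] = n_independent
    report["satisfied"] = ok
    return ok, report
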