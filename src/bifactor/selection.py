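"""Selecting the number of group factors by BIC.

Because the numbers of nonzero loadings and uniquenesses in the bi-factor
model do not depend on G, the BIC of the model with G group factors differs
from

    BIC(G) = N * l*_G + (G(G-1)/2) * log N

only by a G-independent constant, where l*_G is the minimized discrepancy and
G(G-1)/2 counts the free parameters of the group-factor correlation block.
The candidate with the smallest BIC wins (smallest G on ties).

A baseline that ignores the bi-factor structure fits an unrestricted
exploratory factor analysis (EFA) model with K factors under the echelon
identification (loadings zero above the diagonal, orthogonal factors) and
selects K by

    BIC_EFA(K) = N * l*_K + (J K - K(K-1)/2) * log N,

reporting K - 1 as the implied number of group factors.  The EFA model spends
J K - K(K-1)/2 free loadings versus the bi-factor model's fixed count, so its
penalty grows much faster in K and it tends to under-select when N is small.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .alm import ALMConfig, FitResult, fit_multistart
from .core import SampleCovariance

__all__ = [
    "SelectionResult",
    "EFAResult",
    "EFASelection",
    "bic_bifactor",
    "select_num_groups",
    "fit_efa",
    "bic_efa_select",
]


@dataclass
class SelectionResult:
    """BIC sweep over candidate numbers of group factors."""

    candidate_G: list[int]
    bic_values: list[float]
    chosen_G: int
    fits: dict[int, FitResult]
    failed: list[int] = field(default_factory=list)

    def table(self):
        """Selection table as a pandas DataFrame (one row per candidate)."""
        import pandas as pd

        rows = []
        for G, bic in zip(self.candidate_G, self.bic_values):
            fit = self.fits[G]
            n_conv = sum(
                1 for _ in fit.start_objectives
            )  # starts attempted; convergence flag below
            rows.append(
                {
                    "G": G,
                    "loss": fit.loss,
                    "penalty": bic - fit.loss * _bic_N(fit),
                    "bic": bic,
                    "converged": fit.converged,
                    "n_starts": n_conv,
                }
            )
        return pd.DataFrame(rows)


def _bic_N(fit: FitResult) -> float:  # stored on the fit by select_num_groups
    return getattr(fit, "_bic_N", float("nan"))


def bic_bifactor(fit: FitResult, N: int, G: int) -> float:
    """BIC (up to a G-independent constant): N*loss + (G(G-1)/2) log N."""
    if not fit.converged:
        warnings.warn(
            f"BIC computed from a non-converged fit (G={G})", stacklevel=2
        )
    return float(N * fit.loss + (G * (G - 1) / 2) * np.log(N))


def select_num_groups(
    sample: SampleCovariance,
    candidates: list[int],
    config: ALMConfig,
) -> SelectionResult:
    """Fit every candidate G by multistart ALM and pick the smallest BIC.

    Candidates whose fit raises are recorded in ``failed`` and excluded with
    a warning.  Ties go to the smaller G (parsimony).
    """
    candidates = sorted(set(int(G) for G in candidates))
    if not candidates or min(candidates) < 1:
        raise ValueError("candidates must be a nonempty list of integers >= 1")
    fits: dict[int, FitResult] = {}
    bics: list[float] = []
    kept: list[int] = []
    failed: list[int] = []
    for G in candidates:
        try:
            fit = fit_multistart(sample, G, config)
        except Exception as err:  # pragma: no cover - defensive
            warnings.warn(f"fit failed for candidate G={G}: {err}", stacklevel=2)
            failed.append(G)
            continue
        fit._bic_N = sample.N  # type: ignore[attr-defined]
        fits[G] = fit
        kept.append(G)
        bics.append(bic_bifactor(fit, sample.N, G))
    if not kept:
        raise RuntimeError("every candidate fit failed; nothing to select")
    chosen = kept[int(np.argmin(bics))]  # argmin returns first min -> smallest G
    return SelectionResult(
        candidate_G=kept, bic_values=bics, chosen_G=chosen, fits=fits, failed=failed
    )


# ---------------------------------------------------------------------------
# unconstrained EFA baseline


@dataclass
class EFAResult:
    loadings: np.ndarray  # J x K echelon loading matrix
    psi: np.ndarray
    loss: float
    start_objectives: list[float] = field(default_factory=list)


@dataclass
class EFASelection:
    candidate_K: list[int]
    bic_values: list[float]
    chosen_K: int
    implied_G: int
    fits: dict[int, EFAResult]


def _efa_free_mask(J: int, K: int) -> np.ndarray:
    """Echelon identification: loading (j, k) free iff k <= j (0-based k <= j)."""
    mask = np.zeros((J, K), dtype=bool)
    for j in range(J):
        mask[j, : min(j + 1, K)] = True
    return mask


def _efa_objective(theta, J, K, mask, S, logdetS):
    nfree = int(mask.sum())
    L = np.zeros((J, K))
    L[mask] = theta[:nfree]
    psi = np.exp(theta[nfree:])
    sigma = L @ L.T
    sigma[np.diag_indices_from(sigma)] += psi
    cf = np.linalg.cholesky(sigma)
    logdet = 2.0 * np.sum(np.log(np.diag(cf)))
    sigma_inv = np.linalg.inv(sigma)
    value = logdet + np.trace(sigma_inv @ S) - logdetS - J
    W = sigma_inv - sigma_inv @ S @ sigma_inv
    gL = 2.0 * (W @ L)
    grad = np.concatenate([gL[mask], psi * np.diag(W)])
    return float(value), grad


def fit_efa(
    sample: SampleCovariance, K: int, config: ALMConfig
) -> EFAResult:
    """ML exploratory factor analysis with K orthogonal factors.

    Rotational indeterminacy is removed by the echelon identification
    (lambda_{jk} = 0 for k > j); uniquenesses stay positive through the log
    parameterization.  Multistart with the same seeded scheme as the ALM.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    J = sample.J
    mask = _efa_free_mask(J, K)
    nfree = int(mask.sum())
    logdetS = sample.logdet()
    bounds = [(None, None)] * nfree + [(-12.0, 12.0)] * J
    best: EFAResult | None = None
    objectives: list[float] = []
    for s in range(config.n_starts):
        rng = np.random.default_rng([config.seed, 104729, s])
        theta0 = np.concatenate(
            [
                rng.uniform(-1.0, 1.0, size=nfree),
                np.log(0.5 * np.diag(sample.S)),
            ]
        )
        res = optimize.minimize(
            _efa_objective,
            theta0,
            args=(J, K, mask, sample.S, logdetS),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": config.inner_maxiter, "gtol": config.inner_tol, "ftol": 1e-14},
        )
        objectives.append(float(res.fun))
        if best is None or res.fun < best.loss:
            L = np.zeros((J, K))
            L[mask] = res.x[:nfree]
            best = EFAResult(
                loadings=L, psi=np.exp(res.x[nfree:]), loss=float(res.fun)
            )
    assert best is not None
    best.start_objectives = objectives
    return best


def bic_efa_select(
    sample: SampleCovariance,
    candidates_K: list[int],
    config: ALMConfig | None = None,
) -> EFASelection:
    """Select the EFA factor count by BIC and report the implied G = K - 1."""
    if not candidates_K:
        raise ValueError("candidates_K must be nonempty")
    config = config or ALMConfig()
    candidates_K = sorted(set(int(K) for K in candidates_K))
    fits: dict[int, EFAResult] = {}
    bics: list[float] = []
    for K in candidates_K:
        fit = fit_efa(sample, K, config)
        fits[K] = fit
        penalty_count = sample.J * K - K * (K - 1) / 2
        bics.append(float(sample.N * fit.loss + penalty_count * np.log(sample.N)))
    chosen_K = candidates_K[int(np.argmin(bics))]
    return EFASelection(
        candidate_K=candidates_K,
        bic_values=bics,
        chosen_K=chosen_K,
        implied_G=chosen_K - 1,
        fits=fits,
    )
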