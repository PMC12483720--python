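"""Augmented Lagrangian solver for equality-constrained ML bi-factor analysis.

The exploratory bi-factor problem is

    minimize  l(Sigma(Lambda, beta, omega), S)
    subject to c(Lambda) = 0,

where ``c`` are the bilinear (or quartic) residuals of
:mod:`bifactor.constraints`.  The augmented Lagrangian for outer iteration t is

    AL(theta) = l(theta) + sum_k m_k c_k(theta) + (mu/2) sum_k c_k(theta)^2,

with multipliers ``m`` and penalty weight ``mu``.  Each outer iteration
minimizes AL over the unconstrained parameters with a quasi-Newton method and
analytic gradients, then applies the first-order multiplier update
``m <- m + mu c`` and grows ``mu`` only when the maximal violation failed to
shrink by the factor ``gamma`` (which keeps the subproblems well conditioned).

The algorithm stops when both the change in (Lambda, Phi, psi) between
consecutive outer iterations and the distance to the bi-factor set fall below
their thresholds.  Because the feasible set is non-convex, the solver is run
from many random starting points and the converged run with the smallest
discrepancy wins; runs that stall within the outer-iteration cap are restarted
from their current parameters with reset multipliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg, optimize

from .constraints import (
    ToleranceConfig,
    bifactor_distance,
    constraint_values,
    extract_structure,
    n_constraints,
    parameter_change,
)
from .core import (
    BiFactorParams,
    GroupCorrelationParams,
    LoadingMatrix,
    SampleCovariance,
    Uniquenesses,
    build_group_correlation,
    discrepancy_loss,
    loss_gradient,
    n_free_beta,
    pack_params,
    unpack_params,
)
from .structure import BiFactorStructure

__all__ = [
    "ALMConfig",
    "ALMState",
    "FitResult",
    "augmented_lagrangian",
    "inner_minimize",
    "update_multipliers",
    "update_penalty",
    "fit_single_start",
    "fit_multistart",
    "identify_solution",
    "random_start",
    "beta_from_correlation",
]

_OMEGA_BOUND = 12.0  # keeps psi in [e^-12, e^12]; Sigma stays well conditioned


@dataclass
class ALMConfig:
    """Tuning constants of the augmented Lagrangian solver.

    Defaults follow the standard multiplier-method recommendations: unit
    initial penalty, ten-fold growth when the violation fails to drop by a
    factor of four, and a cap preventing ill-conditioned subproblems.
    """

    mu0: float = 1.0
    rho: float = 10.0
    gamma: float = 0.25
    mu_max: float = 1e8
    max_outer: int = 100
    max_restarts: int = 3
    n_starts: int = 50
    seed: int = 0
    tolerances: ToleranceConfig = field(default_factory=ToleranceConfig)
    inner_tol: float = 1e-7
    inner_maxiter: int = 500
    constraint_form: str = "pairwise"
    verbose: int = 0

    def __post_init__(self) -> None:
        if not (self.rho > 1 and 0 < self.gamma < 1 and self.mu0 > 0):
            raise ValueError("require rho > 1, 0 < gamma < 1, mu0 > 0")
        if min(self.mu_max, self.max_outer, self.n_starts, self.inner_maxiter) <= 0:
            raise ValueError("caps and start counts must be positive")

    @classmethod
    def profile(cls, name: str, **overrides) -> "ALMConfig":
        """Named tolerance profiles: 'simulation' (eps1=1e-4, eps2=1e-3) or
        'accurate' (eps1=1e-5, eps2=1e-4) for final real-data fits."""
        if name == "simulation":
            tol = ToleranceConfig(1e-4, 1e-3)
        elif name == "accurate":
            tol = ToleranceConfig(1e-5, 1e-4)
        else:
            raise ValueError(f"unknown profile {name!r}; use 'simulation' or 'accurate'")
        return cls(tolerances=tol, **overrides)


@dataclass
class ALMState:
    """Mutable solver state: iterate, multipliers, penalty, history."""

    params: BiFactorParams
    multipliers: np.ndarray
    mu: float
    outer_iter: int = 0
    history: list[dict] = field(default_factory=list)
    constraint_form: str = "pairwise"


@dataclass
class FitResult:
    """Outcome of one (or the best of many) ALM run."""

    params: BiFactorParams
    structure: BiFactorStructure | None
    loss: float
    converged: bool
    n_starts_used: int = 1
    start_objectives: list[float] = field(default_factory=list)
    diagnostics: list[dict] = field(default_factory=list)
    restarts_used: int = 0

    @property
    def G(self) -> int:
        return self.params.G


def augmented_lagrangian(
    params: BiFactorParams, state: ALMState, sample: SampleCovariance
) -> float:
    """Value of the augmented Lagrangian at ``params`` under ``state``."""
    c = constraint_values(params.loadings, state.constraint_form).values
    loss = discrepancy_loss(params, sample)
    return float(loss + state.multipliers @ c + 0.5 * state.mu * (c @ c))


def _al_value_grad(
    theta: np.ndarray,
    J: int,
    G: int,
    sample: SampleCovariance,
    multipliers: np.ndarray,
    mu: float,
    form: str,
) -> tuple[float, np.ndarray]:
    """Augmented Lagrangian and its gradient over the flat parameter vector."""
    params = unpack_params(theta, J, G)
    loss = discrepancy_loss(params, sample)
    g_lam, g_beta, g_omega = loss_gradient(params, sample)

    B = params.loadings.group
    value = loss
    gB = np.zeros_like(B)
    if G > 1:
        iu, ju = np.triu_indices(G, k=1)
        pair = B[:, iu] * B[:, ju]  # J x P
        if form == "pairwise":
            c = pair.ravel()
            a = (multipliers + mu * c).reshape(B.shape[0], -1)
            value += multipliers @ c + 0.5 * mu * (c @ c)
            for p in range(iu.size):
                gB[:, iu[p]] += a[:, p] * B[:, ju[p]]
                gB[:, ju[p]] += a[:, p] * B[:, iu[p]]
        else:  # row_aggregate: c_j = sum_p pair_{jp}^2
            c = np.sum(pair**2, axis=1)
            a = multipliers + mu * c  # length J
            value += multipliers @ c + 0.5 * mu * (c @ c)
            T = np.sum(B**2, axis=1, keepdims=True)
            gB += a[:, None] * 2.0 * B * (T - B**2)
    g_lam = g_lam.copy()
    g_lam[:, 1:] += gB
    grad = np.concatenate([g_lam.ravel(), g_beta, g_omega * 1.0])
    return float(value), grad


def inner_minimize(state: ALMState, sample: SampleCovariance, config: ALMConfig) -> BiFactorParams:
    """Approximately minimize the augmented Lagrangian at fixed multipliers/mu.

    Uses L-BFGS-B with analytic gradients; stops when the projected gradient
    norm falls below ``config.inner_tol`` or after ``config.inner_maxiter``
    iterations.  ``omega`` is box-bounded purely for numerical conditioning.
    """
    params = state.params
    J, G = params.J, params.G
    theta0 = pack_params(params)
    n_lam = J * (G + 1)
    n_beta = n_free_beta(G)
    bounds = [(None, None)] * (n_lam + n_beta) + [(-_OMEGA_BOUND, _OMEGA_BOUND)] * J
    res = optimize.minimize(
        _al_value_grad,
        theta0,
        args=(J, G, sample, state.multipliers, state.mu, state.constraint_form),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={
            "maxiter": config.inner_maxiter,
            "gtol": config.inner_tol,
            "ftol": 1e-14,
        },
    )
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError("inner minimization produced non-finite parameters")
    return unpack_params(res.x, J, G)


def update_multipliers(state: ALMState) -> np.ndarray:
    """First-order multiplier update m <- m + mu * c at the current iterate."""
    c = constraint_values(state.params.loadings, state.constraint_form).values
    state.multipliers = state.multipliers + state.mu * c
    return state.multipliers


def update_penalty(state: ALMState, prev_violation: float, config: ALMConfig) -> float:
    """Grow mu by rho (capped at mu_max) unless the maximal violation dropped
    by at least the factor gamma."""
    c = constraint_values(state.params.loadings, state.constraint_form)
    if c.max_abs > config.gamma * prev_violation:
        state.mu = min(config.rho * state.mu, config.mu_max)
    return state.mu


def fit_single_start(
    sample: SampleCovariance,
    G: int,
    config: ALMConfig,
    start: BiFactorParams,
) -> FitResult:
    """Run the ALM from one starting point, with the restart policy.

    Iterates inner minimization / multiplier update / penalty update until the
    parameter change drops below eps_param and the distance to the bi-factor
    set below eps_struct.  If the outer-iteration cap is hit, the solver
    restarts from the current parameters with multipliers reset to zero and
    mu reset to mu0, up to ``config.max_restarts`` times.
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    start_loss = discrepancy_loss(start, sample)
    if not np.isfinite(start_loss):
        raise ValueError("non-finite discrepancy at the starting parameters")

    eps1 = config.tolerances.eps_param
    eps2 = config.tolerances.eps_struct
    m0 = np.zeros(n_constraints(sample.J, G, config.constraint_form))
    state = ALMState(
        params=start,
        multipliers=m0.copy(),
        mu=config.mu0,
        constraint_form=config.constraint_form,
    )
    converged = False
    restarts = 0
    history: list[dict] = []
    while True:
        prev_violation = np.inf
        prev_params: BiFactorParams | None = None
        for _ in range(config.max_outer):
            state.params = inner_minimize(state, sample, config)
            state.outer_iter += 1
            c = constraint_values(state.params.loadings, state.constraint_form)
            dist = bifactor_distance(state.params.loadings)
            loss = discrepancy_loss(state.params, sample)
            change = (
                parameter_change(prev_params, state.params)
                if prev_params is not None
                else np.inf
            )
            history.append(
                {
                    "outer_iter": state.outer_iter,
                    "loss": loss,
                    "max_abs_c": c.max_abs,
                    "distance": dist,
                    "param_change": change,
                    "mu": state.mu,
                }
            )
            if config.verbose >= 2:
                print(
                    f"  outer {state.outer_iter:3d}  loss {loss:.6e}  "
                    f"max|c| {c.max_abs:.2e}  dist {dist:.2e}  mu {state.mu:.1e}"
                )
            if change < eps1 and dist < eps2:
                converged = True
                break
            prev_params = state.params.copy()
            update_multipliers(state)
            update_penalty(state, prev_violation, config)
            prev_violation = c.max_abs
        if converged or restarts >= config.max_restarts:
            break
        # restart from current estimates with fresh auxiliary coefficients
        restarts += 1
        state.multipliers = m0.copy()
        state.mu = config.mu0
    structure = (
        extract_structure(state.params.loadings, eps2) if converged else None
    )
    return FitResult(
        params=state.params,
        structure=structure,
        loss=discrepancy_loss(state.params, sample),
        converged=converged,
        diagnostics=history,
        restarts_used=restarts,
    )


def random_start(
    sample: SampleCovariance, G: int, rng: np.random.Generator
) -> BiFactorParams:
    """Random starting point: loadings ~ U(-1, 1), beta ~ U(-0.5, 0.5),
    psi_j = 0.5 * S_jj."""
    J = sample.J
    lam = rng.uniform(-1.0, 1.0, size=(J, G + 1))
    beta = rng.uniform(-0.5, 0.5, size=n_free_beta(G))
    psi = 0.5 * np.diag(sample.S).copy()
    return BiFactorParams(
        LoadingMatrix(lam), GroupCorrelationParams(beta), Uniquenesses(psi)
    )


def fit_multistart(
    sample: SampleCovariance, G: int, config: ALMConfig
) -> FitResult:
    """Best-of-``n_starts`` ALM fit; deterministic given ``config.seed``.

    Each start draws its own seeded random initial point.  The winner is the
    converged run with the smallest discrepancy (first on ties); if no start
    converges, the best non-converged run is returned flagged accordingly.
    """
    results: list[FitResult] = []
    objectives: list[float] = []
    for s in range(config.n_starts):
        rng = np.random.default_rng([config.seed, s])
        start = random_start(sample, G, rng)
        res = fit_single_start(sample, G, config, start)
        results.append(res)
        objectives.append(res.loss)
        if config.verbose >= 1:
            print(
                f"start {s:2d}: loss {res.loss:.6e} "
                f"{'converged' if res.converged else 'NOT converged'}"
            )
    converged = [r for r in results if r.converged]
    pool = converged if converged else results
    best = min(pool, key=lambda r: r.loss)
    if not converged:
        warnings.warn(
            "no ALM start converged; returning best non-converged solution",
            stacklevel=2,
        )
    return replace(
        best,
        n_starts_used=config.n_starts,
        start_objectives=objectives,
    )


def beta_from_correlation(phi_g: np.ndarray) -> np.ndarray:
    """Invert the row-normalized Cholesky map on a PD correlation matrix."""
    G = phi_g.shape[0]
    if G <= 1:
        return np.empty(0)
    L = linalg.cholesky(phi_g, lower=True)
    beta = np.empty(n_free_beta(G))
    pos = 0
    for g in range(1, G):
        beta[pos : pos + g] = L[g, :g] / L[g, g]
        pos += g
    # round trip sanity under degenerate conditioning
    if not np.all(np.isfinite(beta)):
        raise linalg.LinAlgError("correlation matrix too ill-conditioned to invert")
    return beta


def identify_solution(
    params: BiFactorParams, eps_struct: float = 1e-3
) -> BiFactorParams:
    """Canonicalize the sign and label indeterminacies of a solution.

    Any solution is equivalent under per-factor sign flips D and relabelings P
    of the group factors, which leave the implied covariance unchanged.  This
    routine flips each factor so its largest-absolute loading is positive and
    orders group factors by the smallest variable index in their extracted
    cluster (empty clusters last, by original position), adjusting Phi
    accordingly.
    """
    lam = params.loadings.values.copy()
    G = params.G
    phi_g = build_group_correlation(params.corr_params, G)

    # sign flips: largest-|.| loading of each column becomes positive
    signs = np.ones(G + 1)
    for k in range(G + 1):
        col = lam[:, k]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            signs[k] = -1.0
    lam = lam * signs
    d = signs[1:]
    phi_g = phi_g * np.outer(d, d)

    # relabel group factors by smallest member variable index
    structure = extract_structure(lam, eps_struct)
    keys = []
    for g, cluster in enumerate(structure.clusters):
        keys.append((0, min(cluster)) if cluster else (1, g))
    order = sorted(range(G), key=lambda g: keys[g])
    lam = np.concatenate([lam[:, :1], lam[:, 1:][:, order]], axis=1)
    phi_g = phi_g[np.ix_(order, order)]
    return BiFactorParams(
        LoadingMatrix(lam),
        GroupCorrelationParams(beta_from_correlation(phi_g)),
        Uniquenesses(params.uniq.psi.copy()),
    )
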