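"""Extended (oblique) bi-factor model: parameterization, covariance, ML discrepancy.

The extended bi-factor model decomposes the population covariance of J observed
variables as

    Sigma = Lambda Phi Lambda' + Psi,

where ``Lambda`` is the J x (G+1) loading matrix (column 0 the general factor,
columns 1..G the group factors), ``Phi`` is the (G+1) x (G+1) factor correlation
matrix with the general factor uncorrelated with every group factor, and ``Psi``
is diagonal with strictly positive uniquenesses.

Free parameters are kept unconstrained:

* loadings enter directly;
* the group-factor correlation block is parameterized by a row-normalized
  lower-triangular Cholesky map with G(G-1)/2 free entries ``beta`` -- every
  finite ``beta`` yields a valid correlation matrix;
* uniquenesses are stored through ``omega = log(psi)``.

The fit function is the normal-theory discrepancy

    l(Sigma, S) = log det Sigma + tr(S Sigma^{-1}) - log det S - J,

which is nonnegative and zero exactly when Sigma = S; N*l differs from
-2 log-likelihood only by a term that does not involve the parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "LoadingMatrix",
    "GroupCorrelationParams",
    "Uniquenesses",
    "BiFactorParams",
    "SampleCovariance",
    "build_group_correlation",
    "build_phi",
    "model_covariance",
    "discrepancy_loss",
    "loss_gradient",
    "pack_params",
    "unpack_params",
    "n_free_beta",
]


def n_free_beta(G: int) -> int:
    """Number of free correlation parameters for G group factors: G(G-1)/2."""
    return G * (G - 1) // 2


@dataclass
class LoadingMatrix:
    """J x (G+1) loading matrix; column 0 is the general factor."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 2:
            raise ValueError(
                "loading matrix must be J x (G+1) with G >= 1; got shape "
                f"{self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("loading matrix contains non-finite entries")
        if self.J < self.G + 1:
            warnings.warn(
                f"J={self.J} < G+1={self.G + 1}: model has more factors than "
                "variables; estimates are unlikely to be identifiable",
                stacklevel=2,
            )

    @property
    def J(self) -> int:
        return self.values.shape[0]

    @property
    def G(self) -> int:
        return self.values.shape[1] - 1

    @property
    def general(self) -> np.ndarray:
        """General-factor column (length J)."""
        return self.values[:, 0]

    @property
    def group(self) -> np.ndarray:
        """J x G block of group-factor loadings."""
        return self.values[:, 1:]


@dataclass
class GroupCorrelationParams:
    """Unconstrained Cholesky-type parameters of the group-correlation block."""

    beta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta contains non-finite entries")


@dataclass
class Uniquenesses:
    """Strictly positive residual variances, stored through omega = log(psi)."""

    psi: np.ndarray

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        if np.any(self.psi <= 0) or not np.all(np.isfinite(self.psi)):
            raise ValueError("uniquenesses must be strictly positive and finite")

    @property
    def omega(self) -> np.ndarray:
        return np.log(self.psi)


@dataclass
class BiFactorParams:
    """Complete parameter triplet (Lambda, beta, psi) of the model."""

    loadings: LoadingMatrix
    corr_params: GroupCorrelationParams
    uniq: Uniquenesses

    def __post_init__(self) -> None:
        G = self.loadings.G
        if self.corr_params.beta.size != n_free_beta(G):
            raise ValueError(
                f"beta has length {self.corr_params.beta.size}, expected "
                f"G(G-1)/2 = {n_free_beta(G)} for G={G}"
            )
        if self.uniq.psi.size != self.loadings.J:
            raise ValueError(
                f"psi has length {self.uniq.psi.size}, expected J={self.loadings.J}"
            )

    @property
    def J(self) -> int:
        return self.loadings.J

    @property
    def G(self) -> int:
        return self.loadings.G

    def phi(self) -> np.ndarray:
        return build_phi(self.corr_params, self.G)

    def copy(self) -> "BiFactorParams":
        return BiFactorParams(
            LoadingMatrix(self.loadings.values.copy()),
            GroupCorrelationParams(self.corr_params.beta.copy()),
            Uniquenesses(self.uniq.psi.copy()),
        )


@dataclass
class SampleCovariance:
    """Sample covariance (or correlation) matrix with its nominal sample size."""

    S: np.ndarray
    N: int
    is_correlation: bool = False
    _logdet: float | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.ndim != 2 or self.S.shape[0] != self.S.shape[1]:
            raise ValueError(f"covariance must be square, got shape {self.S.shape}")
        asym = np.max(np.abs(self.S - self.S.T))
        if asym > 1e-10:
            raise ValueError(f"covariance not symmetric (max asymmetry {asym:.3e})")
        self.S = 0.5 * (self.S + self.S.T)
        lam_min = linalg.eigvalsh(self.S)[0]
        if lam_min < -1e-10:
            raise ValueError(
                f"covariance has negative eigenvalue {lam_min:.3e}; not PSD"
            )

    @property
    def J(self) -> int:
        return self.S.shape[0]

    def logdet(self) -> float:
        """log det S, cached; raises if S is numerically singular."""
        if self._logdet is None:
            sign, val = np.linalg.slogdet(self.S)
            if sign <= 0 or not np.isfinite(val):
                cond = np.linalg.cond(self.S)
                raise linalg.LinAlgError(
                    "sample covariance is singular or indefinite "
                    f"(condition number {cond:.3e}); supply more observations, "
                    "use a correlation matrix, or add a ridge"
                )
            self._logdet = float(val)
        return self._logdet

    @classmethod
    def from_data(
        cls, X: np.ndarray, denominator: str = "ml", is_correlation: bool = False
    ) -> "SampleCovariance":
        """Form the sample covariance of an N x J data matrix.

        ``denominator='ml'`` divides by N (maximum-likelihood convention,
        the default); ``'unbiased'`` divides by N-1.  With
        ``is_correlation=True`` the matrix is rescaled to a correlation
        matrix, equivalent to analysing standardized variables.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("data must be a 2-d N x J array")
        N = X.shape[0]
        Xc = X - X.mean(axis=0)
        ddof = 0 if denominator == "ml" else 1
        if denominator not in ("ml", "unbiased"):
            raise ValueError("denominator must be 'ml' or 'unbiased'")
        S = Xc.T @ Xc / (N - ddof)
        if is_correlation:
            d = np.sqrt(np.diag(S))
            S = S / np.outer(d, d)
            np.fill_diagonal(S, 1.0)
        return cls(S=S, N=N, is_correlation=is_correlation)


def build_group_correlation(beta, G: int) -> np.ndarray:
    """Map unconstrained parameters to the G x G group-factor correlation matrix.

    Row g of a lower-triangular matrix L is (beta_{g,1..g-1}, 1, 0, ..., 0)
    scaled to unit Euclidean norm, and the result is L L'.  The map is smooth
    and surjective onto the set of correlation matrices: every finite beta
    gives a symmetric positive-definite matrix with unit diagonal.
    """
    if isinstance(beta, GroupCorrelationParams):
        beta = beta.beta
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    expected = n_free_beta(G)
    if beta.size != expected:
        raise ValueError(
            f"beta has length {beta.size}, expected G(G-1)/2 = {expected} for G={G}"
        )
    L = _cholesky_rows(beta, G)
    phi = L @ L.T
    np.fill_diagonal(phi, 1.0)
    return phi


def _cholesky_rows(beta: np.ndarray, G: int) -> np.ndarray:
    """Row-normalized lower-triangular factor L with L L' a correlation matrix."""
    L = np.zeros((G, G))
    pos = 0
    for g in range(G):
        row = np.zeros(G)
        row[:g] = beta[pos : pos + g]
        row[g] = 1.0
        pos += g
        L[g] = row / np.sqrt(row @ row)
    return L


def build_phi(beta, G: int) -> np.ndarray:
    """Full (G+1) x (G+1) factor correlation matrix.

    The general factor (index 0) is uncorrelated with every group factor by
    construction; the lower-right G x G block comes from
    :func:`build_group_correlation`.
    """
    phi = np.zeros((G + 1, G + 1))
    phi[0, 0] = 1.0
    phi[1:, 1:] = build_group_correlation(beta, G)
    return phi


def model_covariance(params: BiFactorParams) -> np.ndarray:
    """Model-implied covariance Sigma = Lambda Phi Lambda' + Psi (symmetric PD)."""
    lam = params.loadings.values
    phi = params.phi()
    sigma = lam @ phi @ lam.T
    sigma[np.diag_indices_from(sigma)] += params.uniq.psi
    return 0.5 * (sigma + sigma.T)


def _sigma_factor(sigma: np.ndarray):
    try:
        return linalg.cho_factor(sigma, lower=True)
    except linalg.LinAlgError as err:  # psi > 0 makes this nearly impossible
        cond = np.linalg.cond(sigma)
        raise linalg.LinAlgError(
            f"model covariance numerically singular (condition number {cond:.3e})"
        ) from err


def discrepancy_loss(params: BiFactorParams, sample: SampleCovariance) -> float:
    """Normal-theory discrepancy l = log det Sigma + tr(S Sigma^-1) - log det S - J.

    Nonnegative, and zero exactly when the model reproduces the sample
    covariance.  N*l equals -2 log-likelihood up to a constant free of the
    parameters, so differences of N*l are likelihood-ratio statistics.
    """
    sigma = model_covariance(params)
    cf = _sigma_factor(sigma)
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(cf[0])))
    trace_term = np.trace(linalg.cho_solve(cf, sample.S))
    return float(logdet_sigma + trace_term - sample.logdet() - sample.J)


def loss_gradient(
    params: BiFactorParams, sample: SampleCovariance
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradient of the discrepancy w.r.t. (Lambda, beta, omega).

    Returns ``(grad_lambda, grad_beta, grad_omega)`` where ``grad_lambda`` is
    J x (G+1).  Uses W = Sigma^-1 (Sigma - S) Sigma^-1:

    * dl/dLambda = 2 W Lambda Phi,
    * dl/dbeta via the chain rule through the row-normalized Cholesky map,
    * dl/domega_j = psi_j * W_jj.
    """
    lam = params.loadings.values
    beta = params.corr_params.beta
    psi = params.uniq.psi
    G = params.G

    phi = params.phi()
    sigma = lam @ phi @ lam.T
    sigma[np.diag_indices_from(sigma)] += psi
    cf = _sigma_factor(0.5 * (sigma + sigma.T))
    sigma_inv = linalg.cho_solve(cf, np.eye(params.J))
    W = sigma_inv - sigma_inv @ sample.S @ sigma_inv
    W = 0.5 * (W + W.T)

    grad_lambda = 2.0 * W @ lam @ phi
    grad_omega = psi * np.diag(W)

    # group-block contribution: dl = tr(A dPhi_G) with A the group block of L'WL
    A = (lam.T @ W @ lam)[1:, 1:]
    grad_beta = np.zeros_like(beta)
    if G > 1:
        L = _cholesky_rows(beta, G)
        AL = A @ L  # dl = 2 sum_{g,c} (A L)_{g,c} dL_{g,c}
        pos = 0
        for g in range(1, G):
            u = np.zeros(G)
            u[:g] = beta[pos : pos + g]
            u[g] = 1.0
            norm = np.sqrt(u @ u)
            Lg = u / norm
            # dL_g/du = (I - Lg Lg')/norm ; du/dbeta_{g,k} = e_k for k < g
            proj = (np.eye(G) - np.outer(Lg, Lg)) / norm
            grad_beta[pos : pos + g] = 2.0 * (AL[g] @ proj)[:g]
            pos += g
    return grad_lambda, grad_beta, grad_omega


# ---------------------------------------------------------------------------
# flat parameter vector used by the optimizer


def pack_params(params: BiFactorParams) -> np.ndarray:
    """Flatten (Lambda, beta, omega) into a single unconstrained vector."""
    return np.concatenate(
        [
            params.loadings.values.ravel(),
            params.corr_params.beta,
            params.uniq.omega,
        ]
    )


def unpack_params(theta: np.ndarray, J: int, G: int) -> BiFactorParams:
    """Inverse of :func:`pack_params` for given dimensions."""
    n_lam = J * (G + 1)
    n_beta = n_free_beta(G)
    if theta.size != n_lam + n_beta + J:
        raise ValueError(
            f"parameter vector has length {theta.size}, expected "
            f"{n_lam + n_beta + J} for J={J}, G={G}"
        )
    lam = theta[:n_lam].reshape(J, G + 1)
    beta = theta[n_lam : n_lam + n_beta]
    omega = theta[n_lam + n_beta :]
    return BiFactorParams(
        LoadingMatrix(lam.copy()),
        GroupCorrelationParams(beta.copy()),
        Uniquenesses(np.exp(omega)),
    )
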