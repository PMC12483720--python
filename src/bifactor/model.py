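"""User-facing Model/Results objects for exploratory bi-factor analysis.

Usage mirrors the common fit-object idiom of statistical modelling packages::

    model = BiFactorModel.from_data(X, n_groups=3)
    results = model.fit(n_starts=50, seed=1)
    print(results.summary())

``BiFactorModel`` holds the sample covariance (built from raw data, a
DataFrame, or supplied directly) and the solver configuration; ``fit``
delegates to the multistart augmented Lagrangian solver and returns a
``BiFactorResults`` with the canonicalized estimates, the learned variable
partition, the discrepancy, BIC, and convergence diagnostics.
``BiFactorModel.select_n_groups`` sweeps candidate G values by BIC.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .alm import ALMConfig, FitResult, fit_multistart, identify_solution
from .constraints import bifactor_distance, extract_structure
from .core import SampleCovariance, build_phi, model_covariance
from .selection import SelectionResult, bic_bifactor, select_num_groups
from .structure import BiFactorStructure

__all__ = ["BiFactorModel", "BiFactorResults"]


class BiFactorModel:
    """Extended (oblique) bi-factor model for a given sample covariance.

    Parameters
    ----------
    cov : SampleCovariance or array-like
        Sample covariance or correlation matrix.  When an array is given,
        ``n_obs`` must be supplied.
    n_groups : int
        Number of group factors G to fit.
    n_obs : int, optional
        Sample size behind the covariance (needed for BIC).
    is_correlation : bool
        Whether the input matrix is a correlation matrix.
    var_names : sequence of str, optional
        Variable names used in summaries; defaults to x1..xJ.
    """

    def __init__(
        self,
        cov,
        n_groups: int,
        n_obs: int | None = None,
        is_correlation: bool = False,
        var_names=None,
    ):
        if isinstance(cov, SampleCovariance):
            self.sample = cov
        else:
            if n_obs is None:
                raise ValueError("n_obs is required when passing a raw matrix")
            self.sample = SampleCovariance(
                S=np.asarray(cov, dtype=float), N=int(n_obs), is_correlation=is_correlation
            )
        if n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        self.n_groups = int(n_groups)
        self.var_names = (
            list(var_names)
            if var_names is not None
            else [f"x{j}" for j in range(1, self.sample.J + 1)]
        )
        if len(self.var_names) != self.sample.J:
            raise ValueError("var_names length does not match J")

    # ------------------------------------------------------------------
    @classmethod
    def from_data(
        cls,
        X,
        n_groups: int,
        denominator: str = "ml",
        standardize: bool = False,
        var_names=None,
    ) -> "BiFactorModel":
        """Build the model from an N x J data matrix."""
        sample = SampleCovariance.from_data(
            np.asarray(X, dtype=float),
            denominator=denominator,
            is_correlation=standardize,
        )
        return cls(sample, n_groups=n_groups, var_names=var_names)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, n_groups: int, denominator: str = "ml",
        standardize: bool = False,
    ) -> "BiFactorModel":
        """Build the model from a DataFrame of observations (columns = items)."""
        return cls.from_data(
            df.to_numpy(dtype=float),
            n_groups=n_groups,
            denominator=denominator,
            standardize=standardize,
            var_names=list(df.columns.astype(str)),
        )

    # ------------------------------------------------------------------
    def fit(
        self,
        n_starts: int = 50,
        seed: int = 0,
        profile: str = "simulation",
        config: ALMConfig | None = None,
        **overrides,
    ) -> "BiFactorResults":
        """Fit by multistart ALM and return a results object.

        ``profile`` picks the stopping tolerances ('simulation' or
        'accurate'); any ALMConfig field can be overridden by keyword.
        """
        if config is None:
            config = ALMConfig.profile(profile, n_starts=n_starts, seed=seed, **overrides)
        raw = fit_multistart(self.sample, self.n_groups, config)
        return BiFactorResults(self, raw, config)

    def select_n_groups(
        self,
        candidates,
        n_starts: int = 10,
        seed: int = 0,
        profile: str = "simulation",
        config: ALMConfig | None = None,
    ) -> SelectionResult:
        """BIC sweep over candidate numbers of group factors."""
        if config is None:
            config = ALMConfig.profile(profile, n_starts=n_starts, seed=seed)
        return select_num_groups(self.sample, list(candidates), config)


class BiFactorResults:
    """Estimates, uncertainty surrogates and diagnostics of a bi-factor fit.

    Attributes
    ----------
    params : BiFactorParams
        Canonicalized estimates (signs flipped so the dominant loading of
        each factor is positive, group factors ordered by first cluster
        member).
    structure : BiFactorStructure
        Learned partition of variables onto group factors.
    loss : float
        Minimized discrepancy value.
    converged : bool
    bic : float
    """

    def __init__(self, model: BiFactorModel, raw: FitResult, config: ALMConfig):
        self.model = model
        self.config = config
        self.raw = raw
        eps2 = config.tolerances.eps_struct
        self.params = identify_solution(raw.params, eps_struct=eps2)
        self.structure = (
            extract_structure(self.params.loadings, eps2)
            if raw.converged
            else None
        )
        self.loss = raw.loss
        self.converged = raw.converged
        self.bic = bic_bifactor(
            replace(raw, params=self.params), model.sample.N, model.n_groups
        )

    # ------------------------------------------------------------------
    @property
    def loadings(self) -> pd.DataFrame:
        """Loading matrix as a DataFrame (general + group columns)."""
        G = self.params.G
        cols = ["general"] + [f"group{g}" for g in range(1, G + 1)]
        return pd.DataFrame(
            self.params.loadings.values, index=self.model.var_names, columns=cols
        )

    @property
    def factor_corr(self) -> pd.DataFrame:
        G = self.params.G
        names = ["general"] + [f"group{g}" for g in range(1, G + 1)]
        return pd.DataFrame(
            build_phi(self.params.corr_params, G), index=names, columns=names
        )

    @property
    def uniquenesses(self) -> pd.Series:
        return pd.Series(self.params.uniq.psi, index=self.model.var_names, name="psi")

    @property
    def fitted_cov(self) -> np.ndarray:
        return model_covariance(self.params)

    @property
    def distance_to_bifactor(self) -> float:
        return bifactor_distance(self.params.loadings)

    def cluster_of(self) -> pd.Series:
        """1-based group label per variable (0 = general factor only)."""
        if self.structure is None:
            raise ValueError("no structure: fit did not converge")
        member = self.structure.membership()
        return pd.Series(
            [member[j] for j in range(1, self.model.sample.J + 1)],
            index=self.model.var_names,
            name="group",
        )

    def summary(self) -> str:
        """Human-readable fit report."""
        lines = []
        J, G = self.model.sample.J, self.model.n_groups
        lines.append("Exploratory bi-factor analysis (equality-constrained ML)")
        lines.append("=" * 60)
        lines.append(
            f"variables: {J}   group factors: {G}   N: {self.model.sample.N}"
        )
        lines.append(
            f"input: {'correlation' if self.model.sample.is_correlation else 'covariance'}"
            f"   starts: {self.raw.n_starts_used}   converged: {self.converged}"
        )
        lines.append(
            f"discrepancy: {self.loss:.6f}   BIC: {self.bic:.2f}   "
            f"distance to bi-factor set: {self.distance_to_bifactor:.2e}"
        )
        lines.append("-" * 60)
        with pd.option_context("display.float_format", "{:8.3f}".format):
            lines.append(str(self.loadings.round(3)))
        if self.structure is not None:
            lines.append("-" * 60)
            for g, cluster in enumerate(self.structure.clusters, start=1):
                names = [self.model.var_names[j - 1] for j in sorted(cluster)]
                lines.append(f"group {g}: {', '.join(names) if names else '(empty)'}")
            if self.structure.unassigned:
                names = [
                    self.model.var_names[j - 1]
                    for j in sorted(self.structure.unassigned)
                ]
                lines.append(f"general only: {', '.join(names)}")
        lines.append("-" * 60)
        with pd.option_context("display.float_format", "{:8.3f}".format):
            lines.append("factor correlations:")
            lines.append(str(self.factor_corr.round(3)))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<BiFactorResults G={self.model.n_groups} loss={self.loss:.4g} "
            f"converged={self.converged}>"
        )
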