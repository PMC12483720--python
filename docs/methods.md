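# Methods

## The model

`bifactor` estimates the extended (oblique) bi-factor model for J observed
variables. The population covariance is decomposed as

    Σ = Λ Φ Λᵀ + Ψ,

where Λ is J×(G+1) (column 0 the general factor, columns 1..G the group
factors), Φ is the factor correlation matrix with Φ₀g = 0 for every group
factor g (the general factor is uncorrelated with all group factors, which is
what makes the structure identifiable rather than rotationally indeterminate),
and Ψ = diag(ψ₁,…,ψ_J) with ψ_j > 0. The bi-factor structure requires each
variable to load on at most one group factor: each row of the group block of Λ
has at most one nonzero entry.

Rather than searching the exponentially many possible cluster assignments,
that combinatorial structure is written as smooth equality constraints

    λ_jg · λ_jg' = 0   for every row j and pair g < g',

which vanish exactly on the set of bi-factor loading matrices. (An aggregate
quartic form, one constraint per row, is available via
`constraint_form="row_aggregate"`; the bilinear pairwise form is the default
because its multipliers are better conditioned.) The estimation problem is

    minimize l(Σ(θ), S)  subject to  c(Λ) = 0,

with the normal-theory discrepancy

    l(Σ, S) = log det Σ + tr(S Σ⁻¹) − log det S − J.

The constant −log det S − J makes the minimum zero at Σ = S; any additive
convention is equivalent because constants cancel in optimization and in BIC
differences. N·l equals −2·log-likelihood up to a parameter-free constant
(verified numerically in the tests).

All free parameters are unconstrained:

* Φ's group block is parameterized by G(G−1)/2 reals β through a
  row-normalized lower-triangular Cholesky map — row g of L is
  (β_{g,1..g−1}, 1, 0, …) scaled to unit norm and Φ_G = LLᵀ. The map is
  smooth and surjective onto the correlation matrices, so no positivity or
  unit-diagonal constraints are ever active.
* Uniquenesses enter as ω = log ψ, keeping Σ positive definite for every
  finite parameter value. (The optimizer additionally boxes ω to ±12 purely
  to avoid pathological conditioning; the bound is never active at solutions
  of well-posed problems.)

Gradients of l through Λ, β and ω are analytic (dl/dΛ = 2WΛΦ with
W = Σ⁻¹(Σ−S)Σ⁻¹, chain rule through the Cholesky map and the exponential)
and checked against central finite differences in the test suite.

## The augmented Lagrangian solver

The constrained problem is solved by the standard multiplier method: outer
iteration t minimizes

    AL(θ) = l(θ) + Σ_k m_k c_k(θ) + (μ/2) Σ_k c_k(θ)²

over θ with L-BFGS (analytic gradients, gradient tolerance `inner_tol = 1e-7`,
at most 500 inner iterations), then updates m ← m + μ·c and grows
μ ← min(ρμ, μ_max) only when max|c| failed to fall by the factor γ. Defaults
follow the usual multiplier-method recommendations: μ₀ = 1, ρ = 10, γ = 0.25,
μ_max = 1e8. Growing μ only on stalls keeps the subproblems well conditioned;
with the multiplier term present, convergence to a feasible point does not
require μ → ∞.

Stopping requires both
(1) the parameter change ‖ΔΛ‖_F + ‖ΔΦ‖_F + ‖Δψ‖₂ < ε₁ between consecutive
outer iterations (unnormalized sum of block norms; thresholds are calibrated
to this convention), and
(2) the distance to the bi-factor set < ε₂, where the distance is the largest
second-largest absolute group loading across rows. Criterion (2) below ε₂
means every row has at most one group loading above ε₂, so the estimated
clusters Î_g = { j : |λ̂_jg| > ε₂ } partition the variables and an exact
bi-factor structure can be read off directly — no post-hoc thresholding
dilemma arises. Two tolerance profiles are provided: `simulation`
(ε₁ = 1e-4, ε₂ = 1e-3), used throughout the studies, and `accurate`
(ε₁ = 1e-5, ε₂ = 1e-4) for final real-data fits.

The feasible set is highly non-convex, so the solver is run from many random
starting points (loadings i.i.d. U(−1,1), β i.i.d. U(−0.5,0.5),
ψ_j = S_jj/2; each start has its own seeded stream) and the converged run
with the smallest discrepancy wins. Runs that exhaust the outer-iteration cap
(100) restart from their current parameters with multipliers reset to zero
and μ reset to μ₀, up to 3 times. 50 starts is a safe default for data-sized
problems; population-covariance demonstrations typically succeed with 5–10.

Reported solutions are canonicalized for the two exact indeterminacies:
each factor's sign is flipped so its largest-absolute loading is positive,
and group factors are relabeled by the smallest variable index in their
cluster. Both operations leave Σ(θ) unchanged.

## Selecting the number of group factors

Since the counts of nonzero loadings and uniquenesses do not depend on G,
BIC differences reduce to

    BIC(G) = N·l*_G + (G(G−1)/2)·log N,

minimized over a candidate set (smallest G on ties). The unrestricted-EFA
baseline fits K orthogonal factors under the echelon identification
(λ_jk = 0 for k > j) and uses

    BIC_EFA(K) = N·l*_K + (J·K − K(K−1)/2)·log N,

reporting K̂ − 1 as the implied number of group factors (uniquenesses appear
in every candidate and are dropped). The EFA penalty counts all free
loadings, so it grows much faster in K than the bi-factor penalty; when N is
too small for the data term to compensate, EFA-BIC systematically
under-selects — the behaviour the simulation study reproduces.

## Synthetic data and study conditions

The generator draws exact bi-factor populations with: general loadings
i.i.d. U(0.5, 1.5); one group loading per variable with magnitude
U(0.5, 1.5) and sign +1 with probability 0.5; β i.i.d. U(−1, 1); ψ_j = 1 for
all j. Approximate populations add off-cluster group loadings with magnitude
U(0, 0.1) and random sign, so the truth lies near but not on the bi-factor
set. Clusters are contiguous equal blocks by default; arbitrary partitions
are accepted. A study fixes the model seed (one draw of Λ₀, Φ₀) and varies
only the data seed across replications; data are i.i.d. mean-zero
multivariate normal with the implied covariance, and the sample covariance
uses the 1/N (ML) denominator by default (1/(N−1) selectable).

The reference grid crosses a small design (J = 15, G = 3, clusters of 5)
and a large design (J = 30, G = 5, clusters of 6) with N ∈ {500, 20000};
the large design at N = 500 is the hardest cell. The two sample sizes are
chosen to straddle the consistency threshold of the EFA-BIC baseline: for
the grid's fixed large-design model draw, the population misfit of a
(G₀)-factor EFA approximation to the (G₀+1)-factor truth is ≈ 0.023, so
EFA-BIC recovers the factor count only once N·0.023 exceeds the ≈ 25·log N
penalty gap, i.e. for N above roughly 1.2·10⁴. N = 500 and N = 20000
therefore probe the two regimes — structure information indispensable vs.
merely helpful. (The misfit, and hence the threshold, depends on the group
correlations of the particular model draw; strongly correlated group factors
make the (G₀+1)-th factor weak and push the threshold up.)

Equal blocks of ≥ 3 variables with continuous loading draws satisfy the
checkable identifiability condition (every cluster ≥ 3 nonzero group
loadings; ≥ 3 groups with group loadings linearly independent of the general
loadings) with probability one; `check_condition3` verifies it instance by
instance rather than by resampling.

What the generator does **not** emulate: non-normal or discrete (Likert)
responses, missing data, unequal uniquenesses, cluster sizes below three, or
model error beyond small loading perturbations. Passing tests therefore
demonstrate correctness of the estimator and its selection behaviour under
the stated normal-theory conditions, not robustness to the violations real
questionnaire data typically exhibit.

## Recovery metrics

* **Loading MSE**: min over group-factor relabelings P and per-factor sign
  flips D of ‖Λ₀ − Λ̂DP‖²_F / (J(G+1)), computed exactly by sign-optimal
  per-column costs plus an optimal assignment (brute-force equivalence over
  all G!·2^{G+1} pairs is asserted in tests). The division by the number of
  loading entries is a normalization convention; it rescales all methods
  equally.
* **EMC**: 1 iff the estimated clusters equal the true clusters up to
  relabeling.
* **ACC**: best-permutation proportion of correctly classified zero/nonzero
  group loadings, (1/(JG))·Σ_g (|I_g ∩ Î_σ(g)| + |I_g^c ∩ Î_σ(g)^c|), again
  via optimal assignment with a brute-force oracle in tests. Variables the
  estimate assigns to no group count as all-zero group-loading rows.
* **SC**: indicator that the selected G equals the truth.

`hard_threshold` implements the post-hoc sparsification used with
rotation-based estimators (group loadings below τ set to zero); it may leave
rows with several surviving loadings, which is precisely the failure mode the
constrained formulation avoids.

## Numerical choices and degenerate inputs

* Singular sample covariances (e.g. N < J) are rejected with the condition
  number reported; correlation input is accepted and flagged through the
  pipeline.
* `second_largest` of a length-1 vector is 0, making G = 1 models trivially
  feasible (the constraint set is empty).
* Extraction ties (two loadings above ε₂, only possible before convergence)
  go to the largest absolute loading, lowest column index on exact ties,
  with a warning.
* BIC ties go to the smaller model.
* Test-suite problem sizes are scaled-down versions of the reference grid
  (e.g. 20 replications with 10 starts in the hardest cell, 5-start
  selection sweeps), chosen so the full suite exercises every study regime
  at desk scale; rate checks use two-sided binomial consistency intervals
  rather than point equality.

## Known limitations

* Only the normal-theory discrepancy ships; the least-squares (Frobenius)
  loss is left as an interface hook.
* No standard errors for the estimates yet: the constrained-ML sampling
  theory (loadings on the boundary of the constraint set) is outside scope;
  the uncertainty surrogate is the multistart objective spread plus the
  convergence diagnostics.
* Local minima are mitigated, not excluded, by multistart; the solver
  reports the objective of every start so flat or multimodal landscapes are
  visible to the user.
* The inequality-relaxed variant (|λ_jg λ_jg'| ≤ c) and hierarchical factor
  extensions are not implemented.
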