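# Methods

## The Gaussian conjugate model and its estimators

`conjugraph` assumes rows of the n×p data matrix are i.i.d. N(0, Σ) and
places the conjugate inverse-Wishart prior Σ ~ IW_p((δ−p−1)D, δ),
δ > p+1, under which E(Σ) = D. Columns are standardized to zero sum and
unit second moment (YⱼᵀYⱼ/n = 1, population-style scaling, not n−1), so
D = I expresses "unit prior variances" and the posterior-mean covariance
is the convex combination α·D + (1−α)·S/n with
α = (δ−p−1)/(δ+n−p−1). Constant columns are an error, not silently
dropped: dropping would change p and every downstream quantity.

The marginal likelihood is available in closed form from matrix-normal ×
inverse-Wishart conjugacy:

    log m(Y) = −(np/2)·ln π + ln Γ_p((δ+n)/2) − ln Γ_p(δ/2)
               + (δ/2)·ln|F| − ((δ+n)/2)·ln|T|,

with F = (δ−p−1)D, T = F + S, and Γ_p the p-dimensional gamma function
(scipy's `multigammaln`). The implementation was validated against direct
numerical quadrature of the univariate integral (p = 1, inverse-gamma
mixture) to 1e−14 before use; the test suite keeps that oracle.

### Empirical Bayes for δ

δ is fitted by maximizing log m(Y), reparameterized by the bounded,
scale-free weight α ∈ (0,1) (δ = p+1+nα/(1−α)): a 100-point grid on
(0.001, 0.999) followed by bounded scalar refinement in the bracketing
interval. With D = I, each evaluation costs O(min(n,p)) using the
singular values of Y (ln|T| = Σ ln(u+σ_k²) + (p−rank)·ln u, u = δ−p−1),
so the whole fit is dominated by one thin SVD. The optimizer returns the
better of the grid point and the refined point; unimodality is not
assumed.

## All-pairs Bayes factors

The 2×2 Schur complement of any pair satisfies
T_{aa.b} = {(T⁻¹)_aa}⁻¹, so every pair's prior/posterior partial
variances and correlations come from the elements of F⁻¹ and T⁻¹ by
elementwise algebra (no per-pair loops): for pair (i,j) with m = T⁻¹
entries and det = m_ii m_jj − m_ij², q_ii = m_jj/det, q_jj = m_ii/det,
q_ij = −m_ij/det, hence rq_ij = −m_ij/√(m_ii m_jj). When n < p and D = I,
T⁻¹ is obtained by the Woodbury identity from an n×n Cholesky solve.

All Bayes-factor arithmetic is in natural logs: the factor
(1−rq²)^{−(δ+n)/2} overflows otherwise. Partial correlations are clipped
to ±(1−1e−12) before logs; clip events are counted and logged (they occur
only in pathological near-collinear inputs). The scaled Bayes factor
divides by (1−rq²)^{(δ+n)/2}, the reading under which evidence increases
with |rq| — the only one compatible with selection consistency, which the
suite verifies empirically (median log sBF of a true edge grows without
bound in n; of a null edge falls).

A Bayes factor against marginal independence (σ_ij = 0) ships as a
supplementary operation: the inverse-Wishart marginalization property
under this mean-preserving parameterization gives the 2×2 marginal block
an IW₂ prior with degrees of freedom δ−p+2, so the conditional formula
applies with F_aa, T_aa in place of the Schur complements. It is validated
by the p = 2 coincidence with the conditional Bayes factor (empty
conditioning set); its degrees-of-freedom convention has no independent
oracle beyond that.

## Exact null tail probabilities and error control

Decomposing T_{aa.b} = F_{aa.b} + Z, the data-driven partial correlation
rz = z_ij/√(z_ii z_jj) has, under the null of conditional independence,
rz² ~ Beta(1/2, (n−1)/2) conditionally on {δ, n, g_ii, g_jj, rg, z_ii,
z_jj}; sBF is monotone in rz² on that conditioning set, so
Pr(sBF > observed) is the Beta survival function at rz² — computed
directly rather than by inverting the sBF→threshold map (same event,
better numerics). Adjustment uses statsmodels' implementations of
Bonferroni, Holm, Benjamini–Hochberg and Benjamini–Yekutieli; the default
is BH at level 0.1, and the graph is the set of pairs whose adjusted
probability falls below the chosen level. n ≥ 3 is required so both Beta
shape parameters are positive.

A caveat the calibration diagnostic makes explicit: the Beta law is exact
under the model in which the regression coefficients of the pair on the
remaining variables carry their conjugate prior. Under data generated with
fixed coefficients, the law holds in the limit of weak prior precision on
those coefficients (u = δ−p−1 large) and degrades for small fixed u (at
u = 2, n = 20 the Kolmogorov–Smirnov distance is ≈ 0.036 over 5000
replicates). The pipeline's empirical-Bayes δ is large whenever the data
are near the global null, and under it the simulated null passes the KS
check comfortably (D ≈ 0.018). `null_calibration_check` therefore runs
the actual pipeline rather than a small fixed δ. Realized family-wise
error under Bonferroni at 10% on independent Gaussian data (p = 25,
n = 50) is ≈ 0.10 over 500 replicates.

## Synthetic-data generators

The generators define the benchmark conditions; their defaults are the
study conditions, not tuning knobs.

**Explicit sparse precisions** (n = 100 benchmarks at p ∈ {200, 500,
1000}): *band* is tridiagonal; *random* permutes the rows/columns of a
band draw; *cluster* is block diagonal with blocks of size 20 whose
within-block off-diagonals are nonzero with probability 0.1; *hub* is
block diagonal with all block edges incident to the block's first node.
Off-diagonal nonzeros are Uniform[−1,1] (exact zeros redrawn so the
support is well defined); the diagonal starts at zero and a constant is
added so the minimum eigenvalue is exactly 0.1. Two readings of that
construction exist for block-diagonal structures: shifting the assembled
matrix once, or shifting each block as it is generated. We generate each
block as a self-contained sparse PD matrix (per-block shift), the reading
consistent with "blocks are sparse matrices"; the global minimum
eigenvalue is 0.1 either way. Blocks truncate when p is not a multiple
of 20.

**G-Wishart precisions** (50-node benchmarks): Φ ~ W_G(b = 4, I), the
Wishart law with density ∝ |K|^{(b−2)/2} exp(−tr(K)/2) restricted to
matrices whose support lies in a given graph. Sampling is by a direct
(exact) sampler rather than a fixed-sweep block Gibbs chain: one
unconstrained Wishart draw (df b+p−1), then cyclic matrix completion of
its inverse over vertex neighborhoods until convergence (tolerance 1e−10,
cap 1000 sweeps; a handful of sweeps suffice for chordal graphs such as
the band). This choice is exact for every graph, faster, and directly
checkable: the complete graph reduces to an ordinary Wishart (moments
verified over 2000 draws), the empty graph to independent χ²_b diagonals
(KS-verified), and non-edges are hard zeros on every draw. The "band"
graph at p = 50 is the path/tridiagonal graph, mirroring the explicit
band structure.

**Misspecification scenarios**: multivariate-t with ν = 3 degrees of
freedom sharing the Gaussian scale matrix; contaminated Gaussian mixing
N(0, Ψ⁻¹) with N(0, 25·Ψ⁻¹) at fraction ε = 0.1; log-Gaussian
(elementwise exp). ν, ε, κ are conventional heavy-tail/contamination
settings, exposed as module constants; benchmarks on these scenarios are
qualitative.

Replicate design: each benchmark dataset redraws its precision matrix.
Fixing one precision per cell makes the cell mean hostage to that single
draw (across-draw SD of per-cell AUCPR means is a few hundredths —
visible as non-monotone-in-p reference values); redrawing per dataset
estimates the mean over draws and gives smooth, reproducible cell means.

What the generators do not emulate: real expression data are not
zero-mean Gaussian with exactly sparse precision — they carry batch
structure, mean effects, heteroskedastic noise and heavier tails than the
t(3) scenario in specific genes. Passing benchmarks here demonstrates
correct ranking and calibration under the stated sampling models, not
performance on any particular real dataset.

## Evaluation conventions

Edge rankings are scored by the negated tail probabilities. AUCROC uses
trapezoidal integration with tie averaging (equivalently the
Mann–Whitney rank statistic, which the tests cross-check to 1e−12).
AUCPR uses step-wise integration over achieved recall levels
(scikit-learn's average precision) with no interpolation between recall
points; interpolating conventions differ from this by well under 0.02 at
the benchmark sizes, and benchmark tolerances account for the convention.

## Numerical choices and limitations

- Determinants, gamma functions and Bayes factors: log space throughout;
  p in the thousands neither overflows nor underflows.
- Ties in edge ranking are broken by (i, j) lexicographic order for
  deterministic output; reruns of the same configuration are
  byte-identical.
- The identity-prior fast path (SVD + Woodbury) activates automatically
  when D = I; a general D takes the dense O(p³) route, with a warning
  above p = 3000.
- Sizes used in the shipped benchmark runs: 50 datasets per cell at
  p ≤ 1000 (a full run is ~3 minutes on one CPU); the calibration
  diagnostic uses 5000 replicates at n = 20, p = 5.
- The linear shrinkage estimator behind the Bayes factors is not a sparse
  estimator; in very sparse, very high-dimensional regimes sparse
  penalized methods can estimate Ω itself better even when edge ranking
  is competitive. The multiple-testing graph controls error rates; it is
  not a joint model fit.
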