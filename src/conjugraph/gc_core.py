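"""Gaussian conjugate (GC) model: standardization, sufficient statistics,
posterior estimators of the covariance and precision matrices, marginal
likelihood, and empirical-Bayes fitting of the prior degrees of freedom.

The model is

    vec(Y) | Sigma ~ N(0, Sigma ⊗ I_n),    Sigma | D, delta ~ IW_p((delta-p-1)D, delta)

with D positive definite and delta > p+1, parameterized so that
E(Sigma) = D.  Conjugacy yields the posterior expectations

    E(Sigma | Y) = {(delta-p-1)D + S} / (delta+n-p-1),   S = Y'Y,
    E(Omega | Y) = (delta+n) {(delta-p-1)D + S}^{-1},

the first being a linear shrinkage estimator alpha*D + (1-alpha)*S/n with
weight alpha = (delta-p-1)/(delta+n-p-1) in (0,1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy.optimize import minimize_scalar
from scipy.special import multigammaln

logger = logging.getLogger("conjugraph")

# Tolerances and knobs used across the package.
STANDARDIZE_TOL = 1e-8          # invariant check on centered/scaled columns
CONSTANT_COL_TOL = 1e-12        # second moment below this => constant column
RQ_CLIP = 1e-12                 # partial correlations clipped to +-(1 - RQ_CLIP)
ALPHA_GRID_SIZE = 100           # coarse grid for empirical-Bayes alpha
ALPHA_BOUNDS = (0.001, 0.999)
DENSE_D_WARN_P = 3000           # warn above this size when D is not identity


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardizedData:
    """Column-standardized data matrix.

    Each column of ``Y`` has zero sum and unit second moment
    (``Y_j' Y_j / n = 1``), the scaling convention under which the prior
    scale D = I means "prior expectation: unit variances".
    """

    Y: np.ndarray
    names: list[str]

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def p(self) -> int:
        return self.Y.shape[1]


def standardize(raw, names=None) -> StandardizedData:
    """Center each column and scale it to unit second moment.

    Parameters
    ----------
    raw : (n, p) array-like or pandas DataFrame
        Samples in rows, variables in columns.  A DataFrame's columns
        provide variable names unless ``names`` is given.
    names : sequence of str, optional
        Variable labels; defaults to the DataFrame columns or ``V1..Vp``.

    Returns
    -------
    StandardizedData

    Raises
    ------
    ValueError
        On missing values, fewer than 3 rows or 2 columns, or a constant
        column (which cannot be scaled to unit second moment).
    """
    if hasattr(raw, "columns"):  # pandas DataFrame
        if names is None:
            names = [str(c) for c in raw.columns]
        raw = raw.to_numpy()
    X = np.asarray(raw, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D samples-by-variables matrix")
    n, p = X.shape
    if n < 3:
        raise ValueError(f"need at least 3 samples, got n={n}")
    if p < 2:
        raise ValueError(f"need at least 2 variables, got p={p}")
    if not np.isfinite(X).all():
        raise ValueError("input matrix contains missing or non-finite values")
    if names is None:
        names = [f"V{j + 1}" for j in range(p)]
    names = [str(s) for s in names]
    if len(names) != p:
        raise ValueError(f"{len(names)} names for {p} columns")

    Xc = X - X.mean(axis=0)
    msq = np.einsum("ij,ij->j", Xc, Xc) / n
    bad = np.flatnonzero(msq <= CONSTANT_COL_TOL)
    if bad.size:
        raise ValueError(
            "constant column(s) cannot be standardized: "
            + ", ".join(names[j] for j in bad[:10])
        )
    Y = Xc / np.sqrt(msq)
    return StandardizedData(Y=Y, names=names)


# ---------------------------------------------------------------------------
# hyperparameters and sufficient statistics
# ---------------------------------------------------------------------------

@dataclass
class GCHyper:
    """Prior hyperparameters (D, delta) with derived quantities.

    ``alpha = (delta-p-1)/(delta+n-p-1)`` is the shrinkage weight of the
    posterior-mean covariance toward D; ``u = delta-p-1`` is the scalar
    multiplying D in the prior matrix F = (delta-p-1) D.  ``D is None``
    denotes the identity prior scale (the fast path).
    """

    delta: float
    p: int
    n: int
    D: np.ndarray | None = None

    def __post_init__(self):
        if self.delta <= self.p + 1:
            raise ValueError(f"delta must exceed p+1 = {self.p + 1}, got {self.delta}")
        if self.D is not None:
            D = np.asarray(self.D, dtype=float)
            if D.shape != (self.p, self.p):
                raise ValueError("D has wrong shape")
            if not np.allclose(D, D.T, atol=1e-10):
                raise ValueError("D must be symmetric")
            if np.linalg.eigvalsh(D)[0] <= 0:
                raise ValueError("D must be positive definite")
            self.D = D

    @property
    def u(self) -> float:
        return self.delta - self.p - 1

    @property
    def alpha(self) -> float:
        return (self.delta - self.p - 1) / (self.delta + self.n - self.p - 1)

    @property
    def F(self) -> np.ndarray:
        D = np.eye(self.p) if self.D is None else self.D
        return self.u * D

    @classmethod
    def from_alpha(cls, alpha: float, p: int, n: int, D=None) -> "GCHyper":
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie strictly in (0, 1)")
        delta = p + 1 + n * alpha / (1 - alpha)
        return cls(delta=delta, p=p, n=n, D=D)


@dataclass
class SufficientStats:
    """Cross-product matrix S = Y'Y with the singular values of Y.

    The singular values drive O(min(n,p)) log-determinant evaluations of
    T = F + S when D = I; ``S`` is materialized lazily and only needed on
    the general-D path.
    """

    Y: np.ndarray
    sing_vals: np.ndarray = field(default=None)
    _S: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.sing_vals is None:
            self.sing_vals = sla.svdvals(self.Y) if self.Y.size else np.array([])

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def p(self) -> int:
        return self.Y.shape[1]

    @property
    def S(self) -> np.ndarray:
        if self._S is None:
            self._S = self.Y.T @ self.Y
        return self._S


def sufficient_stats(data: StandardizedData) -> SufficientStats:
    return SufficientStats(Y=data.Y)


# ---------------------------------------------------------------------------
# posterior estimators
# ---------------------------------------------------------------------------

def posterior_covariance(stats: SufficientStats, hyper: GCHyper) -> np.ndarray:
    """Posterior mean of Sigma: {(delta-p-1)D + S} / (delta+n-p-1)."""
    n, p = stats.n, stats.p
    if hyper.p != p or hyper.n != n:
        raise ValueError("hyperparameters inconsistent with data dimensions")
    return (hyper.F + stats.S) / (hyper.delta + n - p - 1)


def posterior_precision(stats: SufficientStats, hyper: GCHyper) -> np.ndarray:
    """Posterior mean of Omega: (delta+n) (F + S)^{-1}."""
    n, p = stats.n, stats.p
    if hyper.p != p or hyper.n != n:
        raise ValueError("hyperparameters inconsistent with data dimensions")
    T = hyper.F + stats.S
    return (hyper.delta + n) * sla.inv(T, check_finite=False)


def inverse_T_fast(data: StandardizedData, hyper: GCHyper) -> np.ndarray:
    """Invert T = F + Y'Y, exploiting the Woodbury identity when D = I.

    With F = u*I (u = delta-p-1) and n < p,

        T^{-1} = (1/u) { I_p - Y' (u I_n + Y Y')^{-1} Y },

    which costs one n-by-n factorization instead of a p-by-p one.  For
    n >= p, or a general D, T is inverted directly.
    """
    Y = data.Y
    n, p = Y.shape
    u = hyper.u
    if u <= 0:
        raise ValueError("delta <= p+1: prior matrix F is not positive definite")
    if hyper.D is None:
        if n < p:
            A = u * np.eye(n) + Y @ Y.T
            c, low = sla.cho_factor(A, check_finite=False)
            B = sla.cho_solve((c, low), Y, check_finite=False)
            Tinv = (np.eye(p) - Y.T @ B) / u
        else:
            T = u * np.eye(p) + Y.T @ Y
            Tinv = sla.inv(T, check_finite=False)
    else:
        if p > DENSE_D_WARN_P:
            warnings.warn(
                f"dense inversion of a {p}x{p} matrix for non-identity D",
                RuntimeWarning,
            )
        Tinv = sla.inv(hyper.F + Y.T @ Y, check_finite=False)
    return (Tinv + Tinv.T) / 2


# ---------------------------------------------------------------------------
# marginal likelihood and empirical Bayes
# ---------------------------------------------------------------------------

def log_marginal_likelihood(stats: SufficientStats, hyper: GCHyper) -> float:
    """Log marginal likelihood of the GC model.

    log m(Y) = -(np/2) ln(pi) + ln Gamma_p((delta+n)/2) - ln Gamma_p(delta/2)
               + (delta/2) ln|F| - ((delta+n)/2) ln|T|,

    with T = F + S.  For D = I the determinants come from the singular
    values of Y: ln|F| = p ln u and ln|T| = sum_k ln(u + s_k^2) with the
    p - rank(S) remaining eigenvalues contributing ln u each.
    """
    n, p = stats.n, stats.p
    delta = hyper.delta
    u = hyper.u
    if n == 0:
        return 0.0
    if hyper.D is None:
        sv2 = stats.sing_vals**2
        logdet_F = p * np.log(u)
        logdet_T = np.sum(np.log(u + sv2)) + (p - sv2.size) * np.log(u)
    else:
        logdet_F = p * np.log(u) + np.linalg.slogdet(hyper.D)[1]
        T = hyper.F + stats.S
        sign, logdet_T = np.linalg.slogdet(T)
        if sign <= 0:
            raise ValueError("T = F + S is not positive definite")
    return (
        -0.5 * n * p * np.log(np.pi)
        + multigammaln((delta + n) / 2, p)
        - multigammaln(delta / 2, p)
        + 0.5 * delta * logdet_F
        - 0.5 * (delta + n) * logdet_T
    )


def log_ml_curve(stats: SufficientStats, alphas: np.ndarray, D=None) -> np.ndarray:
    """Log marginal likelihood evaluated on a grid of shrinkage weights."""
    n, p = stats.n, stats.p
    return np.array(
        [
            log_marginal_likelihood(stats, GCHyper.from_alpha(a, p, n, D=D))
            for a in np.asarray(alphas)
        ]
    )


def fit_delta_empirical_bayes(
    data: StandardizedData, D: np.ndarray | None = None
) -> GCHyper:
    """Empirical-Bayes estimate of delta by marginal-likelihood maximization.

    The search runs over the bounded reparameterization
    alpha = (delta-p-1)/(delta+n-p-1) in (0,1): a coarse grid
    (ALPHA_GRID_SIZE points) followed by bounded scalar refinement around
    the grid optimum.  Returns the fitted :class:`GCHyper`.
    """
    stats = sufficient_stats(data)
    n, p = stats.n, stats.p
    lo, hi = ALPHA_BOUNDS
    grid = np.linspace(lo, hi, ALPHA_GRID_SIZE)
    vals = log_ml_curve(stats, grid, D=D)
    k = int(np.argmax(vals))
    a_lo = grid[max(k - 1, 0)]
    a_hi = grid[min(k + 1, grid.size - 1)]

    def neg(a):
        return -log_marginal_likelihood(stats, GCHyper.from_alpha(a, p, n, D=D))

    alpha_hat = grid[k]
    try:
        res = minimize_scalar(neg, bounds=(a_lo, a_hi), method="bounded")
        if res.success:
            # keep the better of grid point and refined point
            if -res.fun >= vals[k]:
                alpha_hat = float(res.x)
        else:
            warnings.warn("alpha refinement failed; using grid optimum", RuntimeWarning)
    except Exception:  # pragma: no cover - scipy failure path
        warnings.warn("alpha refinement raised; using grid optimum", RuntimeWarning)
    hyper = GCHyper.from_alpha(alpha_hat, p, n, D=D)
    logger.info(
        "empirical Bayes: alpha=%.4f delta=%.2f (n=%d, p=%d)",
        hyper.alpha, hyper.delta, n, p,
    )
    return hyper
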