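"""Synthetic data: sparse precision matrices, G-Wishart draws, noise scenarios.

Two generators for the true precision matrix of a zero-mean Gaussian
graphical model:

* ``make_precision_explicit`` — band / cluster / hub / random support with
  off-diagonal nonzeros drawn Uniform[-1, 1] and the diagonal shifted so
  the minimum eigenvalue equals 0.1 exactly;
* ``sample_gwishart`` — a draw from the G-Wishart distribution W_G(b, D)
  (density proportional to |K|^{(b-2)/2} exp(-tr(DK)/2) restricted to
  matrices with support in a given graph), via a direct sampler: one
  unconstrained Wishart draw followed by cyclic matrix completion.

``sample_data`` then draws n Gaussian samples with covariance K^{-1}, or
one of three misspecification scenarios (multivariate-t, contaminated
Gaussian, log-Gaussian) sharing the same scale matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy import stats as sps

STRUCTURES = ("band", "cluster", "hub", "random")
NOISE_SCENARIOS = ("gaussian", "multivariate_t", "contaminated", "log_gaussian")
MIN_EIGENVALUE = 0.1     # target smallest eigenvalue of explicit precisions
BLOCK_SIZE = 20          # cluster / hub block size
CLUSTER_DENSITY = 0.1    # within-block off-diagonal density for cluster
# Heavy-tail / contamination defaults for the misspecification scenarios.
T_DOF = 3.0
CONTAM_FRACTION = 0.1
CONTAM_SCALE = 25.0
GWISHART_TOL = 1e-10
GWISHART_MAX_SWEEPS = 1000


@dataclass
class SimScenario:
    """A fully specified simulation condition.

    ``precision`` is the true inverse covariance (called Psi for the
    explicit generator, Phi for G-Wishart draws); ``true_edges`` is its
    exact off-diagonal support as a set of 0-based (i, j) pairs with i < j.
    """

    structure: str
    p: int
    n: int
    generator: str          # "explicit" or "gwishart"
    noise: str
    seed: int
    precision: np.ndarray
    true_edges: frozenset = field(default=None)

    def __post_init__(self):
        if self.noise not in NOISE_SCENARIOS:
            raise ValueError(f"unknown noise scenario {self.noise!r}")
        if self.true_edges is None:
            self.true_edges = support_edges(self.precision)

    @property
    def truth_vector(self) -> np.ndarray:
        """Boolean edge indicator over the upper triangle (pair order)."""
        iu, ju = np.triu_indices(self.p, k=1)
        adj = np.zeros((self.p, self.p), dtype=bool)
        for i, j in self.true_edges:
            adj[i, j] = True
        return adj[iu, ju]


def support_edges(K: np.ndarray, tol: float = 0.0) -> frozenset:
    """Off-diagonal support of a symmetric matrix as {(i, j), i < j}."""
    p = K.shape[0]
    iu, ju = np.triu_indices(p, k=1)
    nz = np.abs(K[iu, ju]) > tol
    return frozenset(zip(iu[nz].tolist(), ju[nz].tolist()))


# ---------------------------------------------------------------------------
# graph skeletons
# ---------------------------------------------------------------------------

def structure_edges(structure: str, p: int, rng: np.random.Generator) -> set:
    """Edge set for one of the four supported structures.

    band: tridiagonal (path) graph.  cluster: blocks of BLOCK_SIZE with
    within-block pairs included independently with probability
    CLUSTER_DENSITY.  hub: blocks of BLOCK_SIZE with all edges incident to
    the first node of the block.  random: the band edge count rewired by a
    uniform permutation of the vertex labels (support size preserved).
    For cluster/hub, a trailing block of size p mod BLOCK_SIZE is kept.
    """
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}; choose from {STRUCTURES}")
    if p < 3:
        raise ValueError("p must be at least 3")
    edges: set = set()
    if structure == "band":
        edges = {(i, i + 1) for i in range(p - 1)}
    elif structure == "random":
        perm = rng.permutation(p)
        edges = {tuple(sorted((int(perm[i]), int(perm[i + 1])))) for i in range(p - 1)}
    else:
        starts = range(0, p, BLOCK_SIZE)
        for s in starts:
            e = min(s + BLOCK_SIZE, p)
            if structure == "hub":
                edges.update((s, k) for k in range(s + 1, e))
            else:  # cluster
                for i in range(s, e):
                    for j in range(i + 1, e):
                        if rng.random() < CLUSTER_DENSITY:
                            edges.add((i, j))
    return edges


def _fill_uniform(K: np.ndarray, edges, rng) -> None:
    """Place Uniform[-1,1] values on the support (exact zeros redrawn)."""
    for i, j in sorted(edges):
        v = rng.uniform(-1.0, 1.0)
        while abs(v) < 1e-10:
            v = rng.uniform(-1.0, 1.0)
        K[i, j] = K[j, i] = v


def _shift_to_min_eig(K: np.ndarray) -> None:
    """Add a constant to the diagonal so the minimum eigenvalue is 0.1."""
    lam_min = sla.eigh(K, eigvals_only=True, subset_by_index=[0, 0])[0]
    K[np.diag_indices_from(K)] += MIN_EIGENVALUE - lam_min


def make_precision_explicit(
    structure: str, p: int, seed: int, n: int = 100, noise: str = "gaussian"
) -> SimScenario:
    """Sparse precision matrix with the stated support pattern.

    Off-diagonal nonzeros are Uniform[-1, 1] (exact zeros redrawn so the
    support is unambiguous); positive definiteness is enforced by adding a
    constant to the diagonal so the minimum eigenvalue equals 0.1.  The
    band matrix is one such matrix; "random" permutes the rows and columns
    of a band draw; cluster and hub are assembled block-diagonally from
    sparse blocks, each generated (and eigenvalue-shifted) independently.
    """
    rng = np.random.default_rng(seed)
    K = np.zeros((p, p))
    if structure in ("band", "random"):
        edges = {(i, i + 1) for i in range(p - 1)}
        _fill_uniform(K, edges, rng)
        _shift_to_min_eig(K)
        if structure == "random":
            perm = rng.permutation(p)
            K = K[np.ix_(perm, perm)]
    elif structure in ("cluster", "hub"):
        for s in range(0, p, BLOCK_SIZE):
            e = min(s + BLOCK_SIZE, p)
            block_edges = {
                (i, j)
                for i in range(s, e)
                for j in range(i + 1, e)
                if (structure == "hub" and i == s)
                or (structure == "cluster" and rng.random() < CLUSTER_DENSITY)
            }
            B = np.zeros((e - s, e - s))
            _fill_uniform(B, {(i - s, j - s) for i, j in block_edges}, rng)
            _shift_to_min_eig(B)
            K[s:e, s:e] = B
    else:
        raise ValueError(f"unknown structure {structure!r}; choose from {STRUCTURES}")
    edges = support_edges(K)
    return SimScenario(
        structure=structure, p=p, n=n, generator="explicit",
        noise=noise, seed=seed, precision=K, true_edges=edges,
    )


# ---------------------------------------------------------------------------
# G-Wishart sampling
# ---------------------------------------------------------------------------

def sample_gwishart(
    edges,
    p: int,
    b: float = 4.0,
    scale: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    tol: float = GWISHART_TOL,
    max_sweeps: int = GWISHART_MAX_SWEEPS,
) -> np.ndarray:
    """Draw a precision matrix from W_G(b, scale) restricted to a graph.

    Direct sampler: (1) draw K from the unconstrained W_G with the complete
    graph — the ordinary Wishart with df b + p - 1 and scale matrix
    ``scale^{-1}`` — and set Sigma = K^{-1}; (2) cyclically complete Sigma*
    so it agrees with Sigma on the diagonal and on graph edges while
    (Sigma*^{-1})_ij = 0 off the graph: for each column j, regress on its
    neighborhood N_j, Sigma*_{-j,j} = Sigma*_{-j,N_j} (Sigma*_{N_j,N_j})^{-1}
    Sigma_{N_j,j}; (3) return K* = (Sigma*)^{-1} with exact zeros imposed
    off-graph.  The completion is iterated to ``tol`` (fast for chordal
    graphs such as the band).

    For the complete graph this reduces to an ordinary Wishart draw; for
    the empty graph the diagonal entries are independent chi-square(b)
    draws (scale = I).
    """
    if b <= 2:
        raise ValueError("G-Wishart degrees of freedom b must exceed 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if scale is None:
        wishart_scale = np.eye(p)
    else:
        wishart_scale = sla.inv(np.asarray(scale, dtype=float))
    df = b + p - 1
    K_full = sps.wishart.rvs(df=df, scale=wishart_scale, random_state=rng)
    adj = np.zeros((p, p), dtype=bool)
    for i, j in edges:
        if i == j:
            raise ValueError("self-loops are not allowed")
        adj[i, j] = adj[j, i] = True

    Sigma = sla.inv(K_full)
    Sigma_star = Sigma.copy()
    neighbors = [np.flatnonzero(adj[j]) for j in range(p)]
    others = [np.delete(np.arange(p), j) for j in range(p)]
    for _ in range(max_sweeps):
        delta_max = 0.0
        for j in range(p):
            Nj, oj = neighbors[j], others[j]
            if Nj.size:
                beta = sla.solve(
                    Sigma_star[np.ix_(Nj, Nj)], Sigma[Nj, j],
                    assume_a="pos", check_finite=False,
                )
                new_col = Sigma_star[np.ix_(oj, Nj)] @ beta
            else:
                new_col = np.zeros(oj.size)
            delta_max = max(delta_max, np.max(np.abs(Sigma_star[oj, j] - new_col)))
            Sigma_star[oj, j] = new_col
            Sigma_star[j, oj] = new_col
        if delta_max < tol:
            break
    K = sla.inv(Sigma_star)
    K = (K + K.T) / 2
    K[~adj & ~np.eye(p, dtype=bool)] = 0.0
    if sla.eigh(K, eigvals_only=True, subset_by_index=[0, 0])[0] <= 0:
        raise RuntimeError("G-Wishart draw is not positive definite")
    return K


def make_scenario_gwishart(
    structure: str, p: int, seed: int, n: int = 100, b: float = 4.0,
    noise: str = "gaussian",
) -> SimScenario:
    """Graph of the given structure with a G-Wishart(b, I) precision draw."""
    rng = np.random.default_rng(seed)
    edges = structure_edges(structure, p, rng)
    K = sample_gwishart(edges, p, b=b, seed=rng)
    return SimScenario(
        structure=structure, p=p, n=n, generator="gwishart",
        noise=noise, seed=seed, precision=K, true_edges=frozenset(edges),
    )


# ---------------------------------------------------------------------------
# data sampling
# ---------------------------------------------------------------------------

def sample_data(scenario: SimScenario, rng=None) -> np.ndarray:
    """Draw the n-by-p data matrix for a scenario (seeded, reproducible).

    gaussian: N(0, K^{-1}).  multivariate_t: the same scale matrix with
    T_DOF degrees of freedom.  contaminated: with probability
    CONTAM_FRACTION a sample is drawn with covariance inflated by
    CONTAM_SCALE.  log_gaussian: elementwise exp of the Gaussian draws.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    K = scenario.precision
    p, n = scenario.p, scenario.n
    lam = sla.eigh(K, eigvals_only=True, subset_by_index=[0, 0])[0]
    if lam <= 0:
        raise ValueError("precision matrix is not positive definite")
    # Sample via the Cholesky factor of K: x = L^{-T} z has covariance K^{-1}.
    L = sla.cholesky(K, lower=True)
    Z = rng.standard_normal((n, p))
    X = sla.solve_triangular(L, Z.T, lower=True, trans="T").T
    if scenario.noise == "gaussian":
        return X
    if scenario.noise == "multivariate_t":
        w = rng.chisquare(T_DOF, size=n) / T_DOF
        return X / np.sqrt(w)[:, None]
    if scenario.noise == "contaminated":
        infl = rng.random(n) < CONTAM_FRACTION
        X[infl] *= np.sqrt(CONTAM_SCALE)
        return X
    if scenario.noise == "log_gaussian":
        return np.exp(X)
    raise ValueError(f"unknown noise scenario {scenario.noise!r}")
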