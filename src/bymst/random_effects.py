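"""Covariance and precision structures for the four random effects.

The hierarchical model decomposes the log-relative-risk surface into

* iid Gaussian heterogeneity (one value per tract),
* a spatially structured Gaussian field with Matern(nu=1) covariance on
  tract centroids,
* a first-order random-walk (RW1) temporal trend, and
* a tract-by-year interaction built from independent RW1 paths over time
  within each tract sharing one precision.

The RW1 is an intrinsic (rank n-1) Gaussian Markov random field with
precision Q = tau * R, where R is the tridiagonal structure matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.special import gammaln, kv

__all__ = [
    "MaternSpec",
    "RW1Spec",
    "matern_correlation",
    "matern_covariance",
    "matern_cholesky",
    "rw1_structure",
    "rw1_logdensity",
    "build_interaction_precision",
]

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class MaternSpec:
    """Marginal variance, scale and (fixed) smoothness of the spatial field."""

    sigma2_sp: float
    kappa: float
    nu: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma2_sp < 0:
            raise ValueError(f"sigma2_sp must be >= 0, got {self.sigma2_sp}")
        if self.kappa <= 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        if self.nu <= 0:
            raise ValueError(f"nu must be > 0, got {self.nu}")


@dataclass
class RW1Spec:
    """Precision and length of an RW1 path; R is built on construction."""

    tau: float
    n: int
    R: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.n < 2:
            raise ValueError(f"RW1 needs length >= 2, got {self.n}")
        self.R = rw1_structure(self.n)

    @property
    def Q(self) -> np.ndarray:
        return self.tau * self.R


def matern_correlation(h, kappa: float, nu: float = 1.0):
    """Matern correlation rho(h) = (kappa*h)^nu K_nu(kappa*h) / (2^(nu-1) Gamma(nu)).

    ``rho(0) = 1`` by continuity.  Accepts scalars or arrays of nonnegative
    distances; returns the same shape.
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be > 0, got {kappa}")
    if nu <= 0:
        raise ValueError(f"nu must be > 0, got {nu}")
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("distances must be nonnegative")
    scalar = h.ndim == 0
    h = np.atleast_1d(h)
    out = np.ones_like(h)
    pos = h > 0
    u = kappa * h[pos]
    log_c = (nu - 1.0) * np.log(2.0) + gammaln(nu)
    with np.errstate(over="ignore", under="ignore", divide="ignore"):
        out[pos] = np.exp(nu * np.log(u) + np.log(kv(nu, u)) - log_c)
    out[pos] = np.clip(out[pos], 0.0, 1.0)
    return float(out[0]) if scalar else out


def matern_covariance(
    distances: np.ndarray,
    spec: MaternSpec,
    jitter: float = 1e-10,
    max_escalations: int = 6,
) -> np.ndarray:
    """Dense Matern covariance on a pairwise distance matrix.

    A diagonal jitter is added and escalated tenfold (at most
    ``max_escalations`` times) until the Cholesky factorization succeeds;
    the returned matrix includes the successful jitter.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    cov = spec.sigma2_sp * matern_correlation(D, spec.kappa, spec.nu)
    _, cov_j = _chol_with_jitter(cov, jitter, max_escalations)
    return cov_j


def matern_cholesky(
    distances: np.ndarray,
    kappa: float,
    nu: float = 1.0,
    jitter: float = 1e-10,
    max_escalations: int = 6,
) -> np.ndarray:
    """Lower Cholesky factor of the unit-variance Matern correlation matrix."""
    D = np.asarray(distances, dtype=float)
    corr = matern_correlation(D, kappa, nu)
    if np.isscalar(corr):
        corr = np.array([[corr]])
    L, _ = _chol_with_jitter(np.atleast_2d(corr), jitter, max_escalations)
    return L


def _chol_with_jitter(mat: np.ndarray, jitter: float, max_escalations: int):
    if jitter <= 0:
        raise ValueError("jitter must be positive")
    n = mat.shape[0]
    eps = jitter
    for _ in range(max_escalations + 1):
        try:
            jittered = mat + eps * np.eye(n)
            return np.linalg.cholesky(jittered), jittered
        except np.linalg.LinAlgError:
            eps *= 10.0
    raise np.linalg.LinAlgError(
        f"covariance not positive definite after jitter escalation to {eps:g} "
        f"(n={n}, min diag={mat.diagonal().min():g})"
    )


def rw1_structure(n: int) -> np.ndarray:
    """RW1 structure matrix R: tridiagonal, diag (1,2,...,2,1), off-diag -1.

    R @ 1 = 0 and rank(R) = n - 1.
    """
    if n < 2:
        raise ValueError(f"RW1 needs length >= 2, got {n}")
    R = 2.0 * np.eye(n) - np.eye(n, k=1) - np.eye(n, k=-1)
    R[0, 0] = 1.0
    R[-1, -1] = 1.0
    return R

def rw1_logdensity(x: np.ndarray, tau: float) -> float:
    """Improper RW1 log-density built from the n-1 increments.

    ((n-1)/2) log(tau/(2 pi)) - (tau/2) sum (x_{t+1} - x_t)^2, i.e. the
    intrinsic GMRF with Q = tau * R normalized with rank(Q) = n-1 powers of
    tau.  Invariant to adding a constant to the path.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("path must be 1-d with length >= 2")
    n = x.size
    quad = float(np.sum(np.diff(x) ** 2))
    return 0.5 * (n - 1) * (np.log(tau) - LOG_2PI) - 0.5 * tau * quad


def rw1_logdensity_rows(paths: np.ndarray, tau: float) -> float:
    """Sum of independent RW1 log-densities over the rows of a 2-d array."""
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    paths = np.asarray(paths, dtype=float)
    n_rows, n = paths.shape
    quad = float(np.sum(np.diff(paths, axis=1) ** 2))
    return n_rows * 0.5 * (n - 1) * (np.log(tau) - LOG_2PI) - 0.5 * tau * quad


def build_interaction_precision(
    n_tracts: int, n_years: int, tau_int: float
) -> sparse.csr_matrix:
    """Block-diagonal interaction precision: one RW1 block per tract.

    Kronecker form I_{n_tracts} x (tau_int * R_{n_years}); the quadratic
    form separates additively over tracts and the rank is
    n_tracts * (n_years - 1).
    """
    if n_tracts < 1:
        raise ValueError(f"n_tracts must be >= 1, got {n_tracts}")
    if n_years < 2:
        raise ValueError(f"n_years must be >= 2, got {n_years}")
    if tau_int <= 0:
        raise ValueError(f"tau_int must be > 0, got {tau_int}")
    R = sparse.csr_matrix(rw1_structure(n_years))
    return sparse.kron(sparse.eye(n_tracts, format="csr"), tau_int * R, format="csr")
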