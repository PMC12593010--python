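"""Penalized Fourier representation and functional PCA of cycle envelopes.

Curves on the 0-100% cycle grid are expanded in an orthonormal Fourier
basis (constant plus ``order`` harmonic sine/cosine pairs, 2*order+1
functions in total) by penalized least squares,

    c_i = argmin  sum_t (x_i(t) - phi(t)'c)^2 + lambda * int (D^2 phi'c)^2,

with the roughness penalty on the second derivative (default
lambda = e^-7).  The sample covariance kernel a(s,t) of the fitted curves
is then eigendecomposed: eigenfunctions xi_k solve

    int a(s,t) xi_k(t) dt = mu_k xi_k(s),

with int xi_k^2 dt = 1 under the trapezoidal inner product on the grid.
Per-curve scores are the projections of the centered curves,
Y_ik = int xi_k(t) (x_i(t) - mean(t)) dt, so Var(Y_.k) = mu_k.  An optional
continuous registration step removes phase variation with a one-parameter
monotone sine warp per curve before the decomposition.

Component retention follows the combined rule: keep the smallest K whose
cumulative variance proportion reaches the floor (default 85%), then drop
trailing components whose eigenvalue does not exceed the eigenvalue floor
(default 1, on the raw covariance scale); at least one component is always
retained.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, optimize

from .exceptions import ConfigurationError, DataError
from .gridops import apply_sine_warp, trapezoid_weights
from .preprocessing import NormalizedCurve


@dataclass(frozen=True)
class BasisSpec:
    """Fourier basis with a second-derivative roughness penalty."""

    order: int = 3                     # harmonics -> 2*order+1 functions
    period: float = 100.0              # % of cycle
    lam: float = math.exp(-7.0)        # roughness-penalty weight

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ConfigurationError("basis order must be >= 1")
        if self.lam < 0:
            raise ConfigurationError("penalty weight must be >= 0")

    @property
    def n_basis(self) -> int:
        return 2 * self.order + 1

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        """Basis matrix Phi (len(grid) x n_basis), orthonormal on [0, T]."""
        T = self.period
        cols = [np.full_like(grid, 1.0 / np.sqrt(T))]
        for k in range(1, self.order + 1):
            wk = 2.0 * np.pi * k / T
            cols.append(np.sqrt(2.0 / T) * np.sin(wk * grid))
            cols.append(np.sqrt(2.0 / T) * np.cos(wk * grid))
        return np.column_stack(cols)

    def penalty_matrix(self) -> np.ndarray:
        """R with c'Rc = int (D^2 phi'c)^2 dt; diagonal for Fourier."""
        diag = [0.0]
        for k in range(1, self.order + 1):
            wk = 2.0 * np.pi * k / self.period
            diag.extend([wk**4, wk**4])
        return np.diag(diag)


@dataclass
class FunctionalDataSet:
    """Basis-coefficient representation of a set of cycle curves."""

    coefficients: np.ndarray           # n_curves x n_basis
    spec: BasisSpec
    grid: np.ndarray
    provenance: list = field(default_factory=list)
    centered: bool = False

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_2d(np.asarray(self.coefficients, float))
        if self.coefficients.shape[1] != self.spec.n_basis:
            raise ValueError("coefficient count per curve must equal 2*order+1")

    @property
    def n_curves(self) -> int:
        return self.coefficients.shape[0]

    def evaluate(self, grid: np.ndarray | None = None) -> np.ndarray:
        """Fitted curves on the grid (n_curves x len(grid))."""
        g = self.grid if grid is None else np.asarray(grid, float)
        return self.coefficients @ self.spec.evaluate(g).T


@dataclass
class FpcaResult:
    """Mean, eigenfunctions, eigenvalues, variance proportions and scores."""

    grid: np.ndarray
    mean: np.ndarray
    eigenfunctions: np.ndarray         # n_components x len(grid)
    eigenvalues: np.ndarray            # descending, >= 0
    proportions: np.ndarray            # eigenvalues / total variance
    scores: np.ndarray                 # n_curves x n_components
    provenance: list = field(default_factory=list)
    n_retained: int | None = None

    @property
    def loadings(self) -> np.ndarray:
        """Scaled loadings sqrt(mu_k) * xi_k (one row per component)."""
        return np.sqrt(self.eigenvalues)[:, None] * self.eigenfunctions

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.tolist(),
            "mean": self.mean.tolist(),
            "eigenfunctions": self.eigenfunctions.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "proportions": self.proportions.tolist(),
            "scores": self.scores.tolist(),
            "provenance": [list(p) for p in self.provenance],
            "n_retained": self.n_retained,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FpcaResult":
        return cls(
            grid=np.asarray(d["grid"], float),
            mean=np.asarray(d["mean"], float),
            eigenfunctions=np.asarray(d["eigenfunctions"], float),
            eigenvalues=np.asarray(d["eigenvalues"], float),
            proportions=np.asarray(d["proportions"], float),
            scores=np.asarray(d["scores"], float),
            provenance=[tuple(p) for p in d.get("provenance", [])],
            n_retained=d.get("n_retained"),
        )


# ---------------------------------------------------------------------------
# basis fitting
# ---------------------------------------------------------------------------

def fit_basis(
    curves: Sequence[NormalizedCurve] | np.ndarray,
    spec: BasisSpec = BasisSpec(),
    grid: np.ndarray | None = None,
    provenance: list | None = None,
) -> FunctionalDataSet:
    """Penalized least-squares Fourier fit of a set of curves.

    ``curves`` is either a sequence of :class:`NormalizedCurve` (which
    carry their own grid and provenance) or a plain n x len(grid) matrix
    with an explicit ``grid``.
    """
    if isinstance(curves, np.ndarray):
        if grid is None:
            raise ValueError("grid is required when passing a plain matrix")
        Y = np.atleast_2d(np.asarray(curves, float))
        g = np.asarray(grid, float)
        prov = provenance or [()] * Y.shape[0]
    else:
        if len(curves) == 0:
            raise DataError("fit_basis needs at least one curve")
        g = curves[0].grid
        for c in curves[1:]:
            if not np.array_equal(c.grid, g):
                raise DataError("all curves must share a common grid")
        Y = np.vstack([c.values for c in curves])
        prov = [c.key for c in curves]

    Phi = spec.evaluate(g)
    A = Phi.T @ Phi + spec.lam * spec.penalty_matrix()
    coef = linalg.solve(A, Phi.T @ Y.T, assume_a="pos").T
    return FunctionalDataSet(coefficients=coef, spec=spec, grid=g, provenance=prov)


# ---------------------------------------------------------------------------
# continuous registration
# ---------------------------------------------------------------------------

def register_curves(
    ds: FunctionalDataSet,
    max_iter: int = 20,
    tol: float = 1e-6,
) -> tuple[FunctionalDataSet, np.ndarray]:
    """Align each curve to the evolving mean with a sine time warp.

    Each curve is re-evaluated at t + a_i sin(pi t / T), with a_i chosen to
    minimize its squared distance to the current cross-sectional mean
    (a_i = 0 is always admissible, so the total cross-sectional variance
    never increases).  Iterated until the mean changes by less than ``tol``
    or ``max_iter`` is reached.  Returns the refitted data set and the
    cumulative warp amplitude per curve.
    """
    if ds.centered:
        raise DataError("register_curves expects uncentered curves")
    grid = ds.grid
    w = trapezoid_weights(grid)
    T = grid[-1]
    bound = 0.99 * T / np.pi          # monotonicity limit of the sine warp
    X0 = ds.evaluate()                # unwarped curves; warps stay absolute
    X = X0.copy()
    amps = np.zeros(ds.n_curves)

    converged = False
    for _ in range(max_iter):
        mean = X.mean(axis=0)
        for i in range(ds.n_curves):
            def sse(a: float, xi=X0[i]) -> float:
                return float(np.sum(w * (apply_sine_warp(grid, xi, a) - mean) ** 2))

            res = optimize.minimize_scalar(
                sse, bounds=(-bound, bound), method="bounded",
                options={"xatol": 1e-7},
            )
            if res.fun < sse(amps[i]):
                amps[i] = float(res.x)
            X[i] = apply_sine_warp(grid, X0[i], amps[i])
        shift = float(np.max(np.abs(X.mean(axis=0) - mean)))
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn("registration did not converge; returning best iterate")

    refit = fit_basis(X, spec=ds.spec, grid=grid, provenance=ds.provenance)
    return refit, amps


# ---------------------------------------------------------------------------
# the eigen decomposition
# ---------------------------------------------------------------------------

def run_fpca(ds: FunctionalDataSet) -> FpcaResult:
    """Functional PCA of a fitted data set.

    The covariance operator is built in the coefficient domain with the
    basis Gram matrix under trapezoidal quadrature on the grid, so the
    decomposition is exactly equivalent to a weighted discrete PCA of the
    fitted curves.  Eigenfunction signs are fixed so the integral over the
    first half-cycle is nonnegative.
    """
    n = ds.n_curves
    if n < 2:
        raise DataError("FPCA needs at least 2 curves")
    grid = ds.grid
    w = trapezoid_weights(grid)
    Phi = ds.spec.evaluate(grid)

    mean_coef = ds.coefficients.mean(axis=0)
    Cc = ds.coefficients - mean_coef
    V = Cc.T @ Cc / n          # population normalization: mu_k = Var(Y_.k)

    W = Phi.T @ (w[:, None] * Phi)           # basis Gram under quadrature
    L = linalg.cholesky(W, lower=True)
    M = L.T @ V @ L
    M = (M + M.T) / 2.0
    vals, vecs = linalg.eigh(M)
    idx = np.argsort(vals)[::-1]
    vals = np.clip(vals[idx], 0.0, None)
    vecs = vecs[:, idx]

    r = min(n - 1, ds.spec.n_basis)
    vals = vals[:r]
    B = linalg.solve_triangular(L.T, vecs[:, :r], lower=False)  # basis coords
    Xi = (Phi @ B).T                                            # r x len(grid)

    # sign convention: nonnegative integral over the first half-cycle
    half = grid <= grid[-1] / 2.0
    for k in range(r):
        s = np.trapezoid(Xi[k][half], grid[half])
        if s < 0:
            Xi[k] = -Xi[k]
            B[:, k] = -B[:, k]

    Xc = Cc @ Phi.T                         # centered fitted curves on grid
    scores = Xc @ (w[:, None] * Xi.T)       # trapezoidal projections

    total = float(vals.sum())
    proportions = vals / total if total > 0 else np.zeros_like(vals)
    return FpcaResult(
        grid=grid,
        mean=Phi @ mean_coef,
        eigenfunctions=Xi,
        eigenvalues=vals,
        proportions=proportions,
        scores=scores,
        provenance=list(ds.provenance),
    )


# ---------------------------------------------------------------------------
# retention and envelopes
# ---------------------------------------------------------------------------

def retain_count(
    eigenvalues: Sequence[float],
    proportions: Sequence[float],
    ev_floor: float = 1.0,
    cum_floor: float = 0.85,
) -> int:
    """Combined retention rule on descending eigenvalue/proportion sequences.

    K is the smallest k whose cumulative variance proportion reaches
    ``cum_floor``, truncated to the leading components whose eigenvalue
    exceeds ``ev_floor``; at least one component is always retained.
    Proportions may be given as fractions or percentages.
    """
    ev = np.asarray(eigenvalues, float)
    prop = np.asarray(proportions, float)
    if prop.sum() > 1.5:                      # percentage scale
        prop = prop / 100.0
    if np.any(np.diff(ev) > 1e-9):
        raise ValueError("eigenvalues must be in descending order")
    cum = np.cumsum(prop)
    reach = np.flatnonzero(cum >= cum_floor - 1e-12)
    k_cum = int(reach[0]) + 1 if reach.size else len(prop)
    k_ev = int(np.sum(ev[:k_cum] > ev_floor))
    if k_ev == 0:
        warnings.warn("no eigenvalue above the floor; retaining one component")
        return 1
    return k_ev


def retain_components(
    result: FpcaResult,
    ev_floor: float = 1.0,
    cum_floor: float = 0.85,
) -> int:
    """Apply the retention rule to a fitted result; records and returns K."""
    K = retain_count(result.eigenvalues, result.proportions, ev_floor, cum_floor)
    result.n_retained = K
    return K


def component_envelopes(
    result: FpcaResult,
    k: int,
    c: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean +/- c * sqrt(mu_k) * xi_k for component ``k`` (1-based).

    These are the positive/negative deviation curves drawn around the mean
    in component plots; the default multiplier is 2.
    """
    if not 1 <= k <= len(result.eigenvalues):
        raise IndexError(f"component {k} out of range 1..{len(result.eigenvalues)}")
    dev = c * np.sqrt(result.eigenvalues[k - 1]) * result.eigenfunctions[k - 1]
    return result.mean + dev, result.mean - dev
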