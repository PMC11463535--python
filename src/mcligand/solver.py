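"""Occupancy optimization: convex QP over the conformer pool, then a
cardinality-constrained MIQP for the parsimonious final selection.

Both stages minimize the residual sum of squares between the observed masked
density and the occupancy-weighted sum of calculated conformer densities,

    rss(ω) = ‖ρ_cᵀ ω − ρ_o‖²,   0 ≤ ω_i ≤ 1,   Σ ω_i ≤ 1.

The MIQP adds indicator variables z_i ∈ {0,1} with z_i·t_min ≤ ω_i ≤ z_i and
Σ z_i ≤ cardinality (3 for X-ray, 2 for cryo-EM; t_min = 0.20): at most
`cardinality` conformers may carry weight, and any nonzero weight is at least
t_min. Because the pool entering the MIQP is small, the integer program is
solved exactly by exhaustive subset enumeration with a closed-form bounded
least-squares solve per subset.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .errors import SolverError

T_MIN_DEFAULT = 0.20
CARDINALITY_XRAY = 3
CARDINALITY_CRYOEM = 2
QP_ZERO_WEIGHT = 1e-6       # QP weights below this are treated as zero
RIDGE_EPS = 1e-10


@dataclass
class QPProblem:
    """rss(ω) data: conformer density rows A and observed vector b."""

    A: np.ndarray               # (n_conformers, n_voxels) calculated density
    b: np.ndarray               # (n_voxels,) observed density

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.b = np.asarray(self.b, dtype=float).ravel()
        if self.A.shape[0] == 0:
            raise SolverError("QP problem has no conformers")
        if self.A.shape[1] != self.b.size:
            raise SolverError(
                f"A has {self.A.shape[1]} voxels but b has {self.b.size}")


@dataclass
class MIQPProblem(QPProblem):
    cardinality: int = CARDINALITY_XRAY
    t_min: float = T_MIN_DEFAULT

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.cardinality < 1:
            raise SolverError("cardinality must be at least 1")
        if not 0.0 < self.t_min < 1.0:
            raise SolverError("t_min must lie strictly between 0 and 1")


@dataclass
class WeightVector:
    """Conformer occupancies ω with the achieved rss objective."""

    weights: np.ndarray
    objective: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < -1e-9) or np.any(self.weights > 1 + 1e-9):
            raise SolverError("weights outside [0, 1]")
        if self.weights.sum() > 1.0 + 1e-8:
            raise SolverError("weights sum exceeds 1")

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.weights > QP_ZERO_WEIGHT)


def _gram(problem: QPProblem) -> tuple[np.ndarray, np.ndarray, float]:
    G = problem.A @ problem.A.T
    h = problem.A @ problem.b
    return G, h, float(problem.b @ problem.b)


def _chol(G: np.ndarray) -> np.ndarray:
    scale = max(np.trace(G) / G.shape[0], 1.0)
    try:
        return np.linalg.cholesky(G)
    except np.linalg.LinAlgError:
        warnings.warn("singular density Gram matrix; applying ridge "
                      f"regularization ε={RIDGE_EPS}", stacklevel=3)
    jitter = RIDGE_EPS * scale
    for _ in range(12):
        try:
            return np.linalg.cholesky(G + jitter * np.eye(G.shape[0]))
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise SolverError("density Gram matrix is not positive semidefinite")


def solve_qp(problem: QPProblem) -> WeightVector:
    """Global minimizer of the convex occupancy QP.

    The problem is reduced to nonnegative least squares on the Cholesky
    factor of the Gram matrix (the upper bounds ω_i ≤ 1 are implied once
    Σω ≤ 1 and ω ≥ 0 hold); the simplex constraint Σω ≤ 1 is enforced by
    bisection on its Lagrange multiplier, along which the constrained sum is
    monotone.
    """
    G, h, bTb = _gram(problem)
    n = G.shape[0]
    L = _chol(G)

    def box_solve(lam: float) -> np.ndarray:
        y = np.linalg.solve(L, h - 0.5 * lam)
        w, _ = nnls(L.T, y)
        return w

    w = box_solve(0.0)
    if w.sum() > 1.0 + 1e-10:
        lo, hi = 0.0, 1.0
        while box_solve(hi).sum() > 1.0:
            lo, hi = hi, hi * 4.0
            if hi > 1e12:   # pragma: no cover
                raise SolverError("sum-constraint multiplier diverged")
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            s = box_solve(mid).sum()
            if s > 1.0:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-12 * max(hi, 1.0):
                break
        w = box_solve(hi)
    w = np.clip(w, 0.0, 1.0)
    total = w.sum()
    if total > 1.0:
        w *= (1.0 - 1e-12) / total
    obj = float(w @ G @ w - 2.0 * h @ w + bTb)
    return WeightVector(weights=w, objective=max(obj, 0.0))


def _enumerate_faces(c: int):
    """All active-set patterns for a subset of size c: per-weight state
    (0 free, 1 at t_min, 2 at 1) × sum-constraint state."""
    for states in itertools.product((0, 1, 2), repeat=c):
        for sum_active in (False, True):
            yield states, sum_active


def _best_over_subsets(G: np.ndarray, h: np.ndarray, bTb: float,
                       subsets: np.ndarray, t_min: float
                       ) -> tuple[float, np.ndarray | None, np.ndarray | None]:
    """Exact minimum of the bounded LS over every subset in `subsets`.

    For each subset the polytope {t_min ≤ ω ≤ 1, Σω ≤ 1} is searched by
    enumerating its faces; on each face the equality-restricted minimizer is
    computed in closed form (batched KKT solves) and kept if feasible. The
    true minimizer of a convex QP over a polytope is the affine-hull
    minimizer of some face, so the best feasible candidate is exact.
    """
    n_sub, c = subsets.shape
    Gs = G[subsets[:, :, None], subsets[:, None, :]]           # (n_sub, c, c)
    hs = h[subsets]                                            # (n_sub, c)
    scale = max(float(np.mean(np.diagonal(Gs, axis1=1, axis2=2))), 1e-30)
    tol = 1e-9
    best_obj = np.full(n_sub, np.inf)
    best_w = np.zeros((n_sub, c))

    bound_val = {1: t_min, 2: 1.0}
    for states, sum_active in _enumerate_faces(c):
        free = [k for k, s in enumerate(states) if s == 0]
        fixed = [k for k, s in enumerate(states) if s != 0]
        v_fixed = np.array([bound_val[states[k]] for k in fixed])
        fixed_sum = float(v_fixed.sum())
        if sum_active and fixed_sum > 1.0 + tol:
            continue
        w = np.zeros((n_sub, c))
        if fixed:
            w[:, fixed] = v_fixed
        if free:
            nf = len(free)
            dim = nf + (1 if sum_active else 0)
            M = np.zeros((n_sub, dim, dim))
            M[:, :nf, :nf] = 2.0 * Gs[:, free][:, :, free]
            M[:, range(nf), range(nf)] += 1e-10 * scale
            rhs = np.zeros((n_sub, dim))
            rhs[:, :nf] = 2.0 * hs[:, free]
            if fixed:
                rhs[:, :nf] -= 2.0 * np.einsum(
                    "sij,j->si", Gs[:, free][:, :, fixed], v_fixed)
            if sum_active:
                M[:, :nf, nf] = 1.0
                M[:, nf, :nf] = 1.0
                rhs[:, nf] = 1.0 - fixed_sum
            try:
                sol = np.linalg.solve(M, rhs[..., None])[..., 0]
            except np.linalg.LinAlgError:    # pragma: no cover
                continue
            w[:, free] = sol[:, :nf]
        elif sum_active and abs(fixed_sum - 1.0) > tol:
            continue
        feasible = np.all(w >= t_min - tol, axis=1) & np.all(w <= 1.0 + tol, axis=1)
        feasible &= w.sum(axis=1) <= 1.0 + tol
        if not feasible.any():
            continue
        wc = np.clip(w, t_min, 1.0)
        sums = wc.sum(axis=1)
        over = sums > 1.0
        wc[over] *= (1.0 / sums[over])[:, None]
        obj = (np.einsum("si,sij,sj->s", wc, Gs, wc)
               - 2.0 * np.einsum("si,si->s", hs, wc) + bTb)
        better = feasible & (obj < best_obj)
        best_obj[better] = obj[better]
        best_w[better] = wc[better]

    k = int(np.argmin(best_obj))
    if not np.isfinite(best_obj[k]):
        return np.inf, None, None
    return float(best_obj[k]), best_w[k], subsets[k]


def solve_miqp(problem: MIQPProblem) -> WeightVector:
    """Exact MIQP solution by exhaustive subset enumeration.

    Every support set of size ≤ cardinality is scored with its optimal
    bounded weights; the empty support (ω = 0) is included, so the returned
    objective never exceeds ‖b‖².
    """
    n = problem.A.shape[0]
    if n > 200:
        raise SolverError(
            f"MIQP pool of {n} candidates exceeds the enumeration limit (200)")
    G, h, bTb = _gram(problem)
    best_obj = bTb                      # empty support
    best = np.zeros(n)
    for size in range(1, min(problem.cardinality, n) + 1):
        subsets = np.array(list(itertools.combinations(range(n), size)), dtype=int)
        obj, w, subset = _best_over_subsets(G, h, bTb, subsets, problem.t_min)
        if w is not None and obj < best_obj - 0.0:
            best_obj = obj
            best = np.zeros(n)
            best[subset] = w
    return WeightVector(weights=best, objective=max(float(best_obj), 0.0))
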