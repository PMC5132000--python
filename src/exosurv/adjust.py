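"""Cluster-robust inference for independence log-likelihoods.

Granules within one cell are correlated (some cells are inherently highly
responding), but the working likelihood treats them as independent.  The
maximum of the independence log-likelihood l_I remains a valid point
estimator; its curvature does not give valid standard errors.  This module
implements the standard repair chain:

* the cluster-robust sandwich variance ``R = H^-1 V H^-1`` with
  ``V = sum_j U_j U_j'`` built from per-cluster score contributions;
* the Chandler–Bate adjusted log-likelihood
  ``l_A(theta) = l_I(C (theta - theta_hat) + theta_hat)`` with
  ``C = N^-1 N_A``, where N and N_A are the symmetric (spectral) square
  roots of ``-H`` and ``R^-1``; l_A keeps the same maximizer but its
  curvature at the optimum equals ``-R^-1``, so likelihood-ratio statistics
  computed from it have the usual chi-square calibration under clustering;
* adjusted likelihood-ratio tests, with the (chi2_0 + chi2_1)/2 mixture
  reference when the null pins a probability to the boundary of the
  parameter space (a one-sided test);
* profile-likelihood confidence intervals based on l_A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from . import numdiff


class InferenceError(RuntimeError):
    pass


def score_by_cluster(cluster_loglik: Callable[[np.ndarray], np.ndarray],
                     theta: np.ndarray) -> np.ndarray:
    """Per-cluster score contributions ``U_j`` at ``theta``.

    ``cluster_loglik`` maps a parameter vector to the length-J vector of
    summed per-cluster log-likelihood contributions.  Returns a (J, p)
    matrix of numerical gradients; at the MLE the column sums vanish.
    """
    scores = numdiff.gradient(cluster_loglik, np.asarray(theta, dtype=float))
    scores = np.atleast_2d(scores)
    if not np.all(np.isfinite(scores)):
        bad = np.unique(np.nonzero(~np.isfinite(scores))[0]).tolist()
        raise InferenceError(f"non-finite score for cluster index(es) {bad}")
    return scores


@dataclass
class SandwichResult:
    """Observed Hessian, outer-product matrix and sandwich variance."""

    H: np.ndarray
    V: np.ndarray
    R: np.ndarray
    robust_se: np.ndarray


def sandwich_variance(H: np.ndarray, scores: np.ndarray) -> SandwichResult:
    """Cluster-robust sandwich ``R = H^-1 V H^-1``, ``V = sum_j U_j U_j'``."""
    H = np.asarray(H, dtype=float)
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    cond = np.linalg.cond(H)
    if not np.isfinite(cond) or cond > 1e12:
        raise InferenceError(
            f"Hessian is numerically singular (condition number {cond:.3g})")
    V = scores.T @ scores
    Hinv = np.linalg.inv(H)
    R = Hinv @ V @ Hinv
    R = 0.5 * (R + R.T)
    diag = np.diag(R)
    if np.any(diag < -1e-10):
        raise InferenceError("sandwich variance has negative diagonal")
    return SandwichResult(H=H, V=V, R=R, robust_se=np.sqrt(np.clip(diag, 0, None)))


def _spd_sqrt(A: np.ndarray, name: str) -> np.ndarray:
    """Symmetric square root from the spectral decomposition; errors if the
    matrix is not positive definite."""
    A = 0.5 * (A + A.T)
    vals, vecs = np.linalg.eigh(A)
    if np.min(vals) <= 0:
        raise InferenceError(
            f"{name} is not positive definite (min eigenvalue {np.min(vals):.3g}); "
            "the optimum may sit on a boundary or there may be too few clusters")
    return vecs @ np.diag(np.sqrt(vals)) @ vecs.T


@dataclass
class AdjustedLikelihood:
    """The adjusted log-likelihood l_A and the pieces that define it."""

    theta_hat: np.ndarray
    C: np.ndarray
    loglik_I: Callable[[np.ndarray], float]
    H: np.ndarray
    R: np.ndarray
    loglik_at_max: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if not np.isfinite(self.loglik_at_max):
            self.loglik_at_max = float(self.loglik_I(self.theta_hat))

    def __call__(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        return float(self.loglik_I(self.C @ (theta - self.theta_hat) + self.theta_hat))


def build_adjustment(H: np.ndarray, R: np.ndarray, theta_hat: np.ndarray,
                     loglik_I: Callable[[np.ndarray], float]) -> AdjustedLikelihood:
    """Construct l_A with curvature ``-R^-1`` at the unchanged maximizer.

    ``N' N = -H`` and ``N_A' N_A = R^-1`` with symmetric square roots from
    spectral decompositions (the positive-definite forms of the observed
    information and the inverse sandwich); ``C = N^-1 N_A``.
    """
    N = _spd_sqrt(-np.asarray(H, dtype=float), "-H (observed information)")
    Rinv = np.linalg.inv(np.asarray(R, dtype=float))
    N_A = _spd_sqrt(Rinv, "R^-1 (inverse sandwich)")
    C = np.linalg.solve(N, N_A)
    return AdjustedLikelihood(theta_hat=np.asarray(theta_hat, float), C=C,
                              loglik_I=loglik_I, H=np.asarray(H, float),
                              R=np.asarray(R, float))


# ---------------------------------------------------------------------------
# constrained maximization helpers

Constraint = dict


def _embed(free: np.ndarray, template: np.ndarray,
           fixed: dict[int, float], ties: Sequence[tuple[int, int]]) -> np.ndarray:
    """Rebuild the full parameter vector from its free coordinates."""
    full = np.array(template, dtype=float)
    free_idx = [k for k in range(full.size)
                if k not in fixed and k not in {b for _, b in ties}]
    full[free_idx] = free
    for k, v in fixed.items():
        full[k] = v
    for a, b in ties:
        full[b] = full[a]
    return full


def maximize_constrained(f: Callable[[np.ndarray], float], x0: np.ndarray,
                         fixed: dict[int, float] | None = None,
                         ties: Sequence[tuple[int, int]] | None = None,
                         bounds: Sequence[tuple[float, float]] | None = None,
                         ) -> tuple[np.ndarray, float]:
    """Maximize f over the coordinates not pinned by ``fixed`` (index ->
    value) or ``ties`` ((a, b) meaning theta_b = theta_a); returns the full
    parameter vector and the attained value."""
    fixed = dict(fixed or {})
    ties = list(ties or [])
    x0 = np.asarray(x0, dtype=float)
    free_idx = [k for k in range(x0.size)
                if k not in fixed and k not in {b for _, b in ties}]
    if not free_idx:
        full = _embed(np.empty(0), x0, fixed, ties)
        return full, float(f(full))
    sub_bounds = ([bounds[k] for k in free_idx] if bounds is not None else None)

    def neg(free: np.ndarray) -> float:
        return -f(_embed(free, x0, fixed, ties))

    res = optimize.minimize(neg, x0[free_idx], method="L-BFGS-B",
                            bounds=sub_bounds,
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    full = _embed(res.x, x0, fixed, ties)
    return full, float(-res.fun)


@dataclass
class LrtResult:
    stat: float
    pvalue: float
    theta_constrained: np.ndarray
    boundary: bool


def mixture_pvalue(stat: float, boundary: bool) -> float:
    """Upper-tail p-value: chi2_1 for an interior null, the 50:50
    (chi2_0 + chi2_1)/2 mixture for a null on the parameter-space boundary
    (equivalent to a one-sided test)."""
    if boundary:
        return float(0.5 * stats.chi2.sf(stat, 1) + (0.5 if stat <= 0 else 0.0))
    return float(stats.chi2.sf(stat, 1))


def lrt_adjusted(adj: AdjustedLikelihood,
                 fixed: dict[int, float] | None = None,
                 ties: Sequence[tuple[int, int]] | None = None,
                 boundary: bool = False,
                 bounds: Sequence[tuple[float, float]] | None = None,
                 tol: float = 1e-6) -> LrtResult:
    """Adjusted likelihood-ratio test of a coordinate or tie constraint.

    ``Lambda_A = 2 (l_A(theta_hat) - l_A(theta_tilde))`` with theta_tilde the
    constrained maximizer of l_A.
    """
    theta_c, ll_c = maximize_constrained(adj, adj.theta_hat, fixed=fixed,
                                         ties=ties, bounds=bounds)
    stat = 2.0 * (adj.loglik_at_max - ll_c)
    if stat < -1e-4:
        raise InferenceError(
            f"constrained optimum exceeds unconstrained (Lambda={stat:.3g}); "
            "the unconstrained fit did not reach the maximum")
    stat = max(stat, 0.0)
    if stat < tol:
        stat = 0.0
    return LrtResult(stat=stat, pvalue=mixture_pvalue(stat, boundary),
                     theta_constrained=theta_c, boundary=boundary)


def profile_ci(adj: AdjustedLikelihood, index: int, level: float = 0.95,
               bounds: Sequence[tuple[float, float]] | None = None,
               max_expand: int = 60) -> tuple[float, float]:
    """Profile-likelihood confidence interval for one working-scale
    coordinate of the adjusted likelihood.

    Endpoints solve ``2 (l_A(theta_hat) - max_nuisance l_A) = q`` with q the
    chi2_1 quantile at ``level``, found by bracketing plus Brent root
    finding.  If the deviance never reaches the quantile before the
    working-scale search box edge (e.g. the natural boundary sqrt(pi) = 0
    for a barely-identified IRP fraction) the box edge itself is returned
    for that side, with a warning that the interval is effectively
    one-sided there.
    """
    q = stats.chi2.ppf(level, 1)
    th = adj.theta_hat
    se0 = float(np.sqrt(max(adj.R[index, index], 1e-12)))
    if bounds is not None:
        lo_box, hi_box = bounds[index]
    else:
        lo_box, hi_box = th[index] - 50 * se0, th[index] + 50 * se0
    warm = {1: th.copy(), -1: th.copy()}

    def deviance(val: float, direction: int) -> float:
        start = warm[direction].copy()
        start[index] = val
        theta_c, ll_c = maximize_constrained(adj, start, fixed={index: val},
                                             bounds=bounds)
        warm[direction] = theta_c
        return 2.0 * (adj.loglik_at_max - ll_c) - q

    def solve_side(direction: int) -> float:
        inner = th[index]
        step = max(se0, 1e-3)
        outer = inner
        for _ in range(max_expand):
            outer = outer + direction * step
            limit = hi_box if direction > 0 else lo_box
            if (direction > 0 and outer >= limit) or (direction < 0 and outer <= limit):
                if deviance(limit, direction) < 0:
                    warnings.warn(
                        f"profile CI endpoint for coordinate {index} lies at or "
                        "beyond the working-scale search bound; reporting an "
                        "open (one-sided) limit", stacklevel=3)
                    return float(limit)
                outer = limit
                break
            if deviance(outer, direction) >= 0:
                break
            inner = outer
            step *= 1.6
        g_in = deviance(inner, direction)
        if g_in > 0:  # flat likelihood right at theta_hat; degenerate
            return th[index]
        return float(optimize.brentq(lambda v: deviance(v, direction),
                                     min(inner, outer), max(inner, outer),
                                     xtol=1e-4 * max(se0, 1e-2)))

    lower = solve_side(-1)
    upper = solve_side(+1)
    return lower, upper
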