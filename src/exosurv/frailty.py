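"""Marginal independence likelihood of the discrete IRP-frailty model.

Each granule carries an unobservable two-point frailty Z (eta with
probability pi_X, else 1) multiplying a piecewise-constant baseline hazard:
one rate during K+ pulses (shared by all pulses, no covariate effect) and one
rate between pulses with a multiplicative diabetes effect.  Averaging the
conditional likelihood over Z gives the per-granule marginal contribution

    l_ij = log[ mu0(t|X)^d * ( pi_X eta^d e^{-eta M0(t|X)}
                               + (1 - pi_X) e^{-M0(t|X)} ) ],

summed over granules under a working independence assumption.  The sum is
maximized on the working scale theta = (alpha1, alpha2, beta2, log eta,
sqrt pi0, sqrt pi1), a reparameterization chosen to make the log-likelihood
close to quadratic.  The square root (rather than a logit) is used for the
IRP probabilities: it is the variance-stabilizing, symmetry-inducing
transform for small probabilities, and it keeps the boundary null pi = 0 at
a *finite* working value — on the logit scale the null sits at -inf where
the likelihood is flat, and the curvature-matching likelihood adjustment of
:mod:`exosurv.adjust` would provably degenerate to the unadjusted test.
Cluster-robust inference on the result lives in :mod:`exosurv.adjust`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from . import numdiff
from .model import EventDataset, FrailtyParams

#: Working-scale box used by the optimizer, the profile CIs and the
#: boundary-constrained refits: (alpha1, alpha2, beta2, log eta, sqrt pi0,
#: sqrt pi1).  pi = 0 is the lower edge of the last two coordinates.
DEFAULT_BOUNDS: tuple[tuple[float, float], ...] = (
    (-25.0, 5.0), (-25.0, 5.0), (-10.0, 10.0),
    (-5.0, 12.0), (0.0, 1.0), (0.0, 1.0),
)

THETA_NAMES = ("alpha1", "alpha2", "beta2", "log_eta",
               "sqrt_pi0", "sqrt_pi1")


def theta_from_params(params: FrailtyParams) -> np.ndarray:
    """Natural -> working scale (log eta, sqrt pi)."""
    return np.array([params.alpha1, params.alpha2, params.beta2,
                     np.log(params.eta), np.sqrt(params.pi0),
                     np.sqrt(params.pi1)])


def params_from_theta(theta: np.ndarray) -> FrailtyParams:
    """Working -> natural scale (pi = theta^2, so any finite-difference
    excursion of the working value keeps pi nonnegative)."""
    theta = np.asarray(theta, dtype=float)
    return FrailtyParams(alpha1=float(theta[0]), alpha2=float(theta[1]),
                         beta2=float(theta[2]), eta=float(np.exp(theta[3])),
                         pi0=float(min(theta[4] ** 2, 1.0)),
                         pi1=float(min(theta[5] ** 2, 1.0)))


@dataclass
class FrailtyData:
    """Sufficient statistics of an event dataset for the frailty likelihood.

    Under the model the likelihood depends on a granule only through its
    pulse exposure, between-pulse exposure, event indicator, the segment
    class at the event and the covariate, so granules sharing these (all
    censored granules of a covariate group, for instance) can be collapsed
    with multiplicity weights.
    """

    e_pulse: np.ndarray
    e_between: np.ndarray
    d: np.ndarray
    event_in_pulse: np.ndarray
    X: np.ndarray
    weight: np.ndarray
    cluster: np.ndarray          # integer codes
    cluster_ids: np.ndarray      # original labels, indexed by the codes

    @classmethod
    def from_dataset(cls, dataset: EventDataset) -> "FrailtyData":
        df = dataset.table
        protocol = dataset.protocol
        t = df["time"].to_numpy()
        expo = protocol.class_exposures(t)
        e_pulse = expo[:, 0] + expo[:, 1]
        e_between = expo[:, 2]
        d = df["event"].to_numpy()
        # segment class at the event; an event at exactly observation_end
        # belongs to the segment just before it
        t_ev = np.minimum(t, np.nextafter(protocol.observation_end, 0.0))
        in_pulse = np.array(
            [protocol.segment_of(ti) != 2 for ti in t_ev]) & (d == 1)
        codes, ids = pd.factorize(df["cell_id"])
        return cls(e_pulse=e_pulse, e_between=e_between, d=d.astype(float),
                   event_in_pulse=in_pulse, X=df["diabetic"].to_numpy(),
                   weight=np.ones(len(df)), cluster=codes,
                   cluster_ids=np.asarray(ids))

    @property
    def n_clusters(self) -> int:
        return int(self.cluster.max()) + 1

    def collapse(self) -> "FrailtyData":
        """Merge granules with identical sufficient statistics (cluster
        identity dropped; only valid for totals, not per-cluster scores)."""
        key = np.column_stack([self.e_pulse, self.e_between, self.d,
                               self.event_in_pulse.astype(float), self.X])
        uniq, inv = np.unique(key, axis=0, return_inverse=True)
        w = np.bincount(inv, weights=self.weight)
        return FrailtyData(
            e_pulse=uniq[:, 0], e_between=uniq[:, 1], d=uniq[:, 2],
            event_in_pulse=uniq[:, 3].astype(bool), X=uniq[:, 4].astype(int),
            weight=w, cluster=np.zeros(len(uniq), dtype=int),
            cluster_ids=np.array(["all"]))


def _per_granule_loglik(theta: np.ndarray, data: FrailtyData) -> np.ndarray:
    a1, a2, b2, log_eta, pt0, pt1 = np.asarray(theta, dtype=float)
    eta = np.exp(log_eta)
    log_between = a2 + b2 * data.X
    m0 = np.exp(a1) * data.e_pulse + np.exp(log_between) * data.e_between
    log_mu0_event = np.where(data.event_in_pulse, a1, log_between)
    # the curvature-adjusted likelihood evaluates this at affinely mapped
    # working points which may overshoot pi = 1 slightly; clip to the
    # boundary (extended-value convention) instead of going non-finite
    pi = np.clip(np.where(data.X == 1, pt1, pt0) ** 2, 0.0, 1.0)
    # log-sum-exp across the two frailty branches: e^{-eta M0} underflows a
    # naive evaluation for eta ~ 500, and pi = 0 gives a clean -inf branch
    with np.errstate(divide="ignore"):
        term_irp = np.log(pi) + data.d * log_eta - eta * m0
        term_base = np.log1p(-pi) - m0
    return data.d * log_mu0_event + np.logaddexp(term_irp, term_base)


def loglik_independence(theta, dataset) -> float:
    """Marginal independence log-likelihood l_I(theta) on the working scale.

    ``dataset`` may be an :class:`EventDataset` or a prebuilt
    :class:`FrailtyData`.
    """
    data = dataset if isinstance(dataset, FrailtyData) else \
        FrailtyData.from_dataset(dataset)
    contrib = _per_granule_loglik(theta, data)
    if not np.all(np.isfinite(contrib)):
        bad = int(np.nonzero(~np.isfinite(contrib))[0][0])
        raise ValueError(
            f"non-finite log-likelihood contribution at record {bad} "
            f"(t={data.e_pulse[bad] + data.e_between[bad]:.4g}, theta={theta})")
    return float(np.dot(data.weight, contrib))


def cluster_logliks(theta: np.ndarray, data: FrailtyData) -> np.ndarray:
    """Length-J vector of per-cluster summed log-likelihood contributions."""
    contrib = data.weight * _per_granule_loglik(theta, data)
    return np.bincount(data.cluster, weights=contrib,
                       minlength=data.n_clusters)


def no_frailty_mle(data: FrailtyData) -> tuple[np.ndarray, float]:
    """Closed-form MLE of the no-frailty submodel (pi0 = pi1 = 0).

    With a single pulse rate and covariate-specific between rates the MLEs
    are event counts over exposures per stratum.  Returns the working-scale
    triple (alpha1, alpha2, beta2) and the submodel log-likelihood.
    """
    w, d = data.weight, data.d

    def rate(events: float, exposure: float) -> float:
        if exposure <= 0:
            return 1e-8
        return max(events, 0.5) / exposure  # 0.5 guard: no events in stratum

    ev_pulse = float(np.sum(w * d * data.event_in_pulse))
    rho1 = rate(ev_pulse, float(np.sum(w * data.e_pulse)))
    mask0, mask1 = data.X == 0, data.X == 1
    ev_b0 = float(np.sum((w * d * ~data.event_in_pulse)[mask0]))
    ev_b1 = float(np.sum((w * d * ~data.event_in_pulse)[mask1]))
    rho2 = rate(ev_b0, float(np.sum((w * data.e_between)[mask0])))
    rho2_diab = rate(ev_b1, float(np.sum((w * data.e_between)[mask1])))
    a = np.array([np.log(rho1), np.log(rho2), np.log(rho2_diab / rho2)])
    theta0 = np.concatenate([a, [0.0, 0.0, 0.0]])
    return a, loglik_independence(theta0, data)


def default_starts(data: FrailtyData) -> list[np.ndarray]:
    """Default starting grid: the no-frailty fit for the rate parameters
    crossed with eta in {10, 100, 1000} and pi in {0.005, 0.02, 0.1}."""
    a, _ = no_frailty_mle(data)
    starts = []
    for eta in (10.0, 100.0, 1000.0):
        for pi in (0.005, 0.02, 0.1):
            starts.append(np.concatenate(
                [a, [np.log(eta), np.sqrt(pi), np.sqrt(pi)]]))
    return starts


@dataclass
class FrailtyFit:
    """Result of maximizing l_I: working-scale MLE, natural-scale
    parameters, observed Hessian and the multi-start record."""

    theta_hat: np.ndarray
    natural: FrailtyParams
    loglik_I: float
    hessian: np.ndarray
    converged: bool
    grad_norm: float
    boundary: bool
    start_points: list[tuple[np.ndarray, float]]
    data: FrailtyData
    cdata: FrailtyData

    def cluster_loglik_fn(self):
        data = self.data
        return lambda th: cluster_logliks(th, data)

    def loglik_fn(self):
        # the collapsed copy gives identical totals at a fraction of the rows
        data = self.cdata
        return lambda th: loglik_independence(th, data)


def fit_frailty(dataset, starts: Sequence[np.ndarray] | None = None,
                tol: float = 1e-12,
                bounds: Sequence[tuple[float, float]] = DEFAULT_BOUNDS,
                frozen: dict[int, float] | None = None,
                compute_hessian: bool = True) -> FrailtyFit:
    """Maximize l_I from multiple starting points.

    ``frozen`` pins working-scale coordinates (index -> value) for
    constrained refits, e.g. ``{5: 0.0}`` for the boundary null pi1 = 0.
    Raises if no start converges; flags boundary solutions (a pi estimate
    within 1e-6 of 0 or 1, or any coordinate at its box edge).
    """
    data = dataset if isinstance(dataset, FrailtyData) else \
        FrailtyData.from_dataset(dataset)
    # collapsed copy for objective evaluations (cluster identity matters only
    # for scores, not for the total log-likelihood)
    cdata = data.collapse()
    frozen = dict(frozen or {})
    if starts is None:
        starts = default_starts(cdata)

    free_idx = [k for k in range(6) if k not in frozen]

    def embed(free: np.ndarray) -> np.ndarray:
        th = np.empty(6)
        th[free_idx] = free
        for k, v in frozen.items():
            th[k] = v
        return th

    def neg(free: np.ndarray) -> float:
        return -loglik_independence(embed(free), cdata)

    record: list[tuple[np.ndarray, float]] = []
    best = None
    n_ok = 0
    for s in starts:
        s = np.asarray(s, dtype=float)
        res = optimize.minimize(
            neg, s[free_idx], method="L-BFGS-B",
            bounds=[bounds[k] for k in free_idx],
            options={"maxiter": 1000, "ftol": tol, "gtol": 1e-9})
        if not np.isfinite(res.fun):
            continue
        n_ok += res.success
        record.append((embed(res.x), float(-res.fun)))
        if best is None or -res.fun > best[1]:
            best = (embed(res.x), float(-res.fun))
    if best is None or n_ok == 0:
        raise RuntimeError("no starting point converged")
    theta_hat, ll = best

    grad = numdiff.gradient(lambda th: loglik_independence(th, cdata), theta_hat)
    at_edge = np.array([
        (k in frozen) or np.isclose(theta_hat[k], bounds[k][0], atol=1e-8)
        or np.isclose(theta_hat[k], bounds[k][1], atol=1e-8)
        for k in range(6)])
    interior_grad = float(np.max(np.abs(grad[~at_edge]))) if np.any(~at_edge) else 0.0
    scale = max(1.0, abs(ll))
    converged = interior_grad < 1e-5 * scale

    natural = params_from_theta(theta_hat)
    boundary = bool(
        min(natural.pi0, natural.pi1, 1 - natural.pi0, 1 - natural.pi1) < 1e-6
        or np.any(at_edge & ~np.isin(np.arange(6), list(frozen))))
    hess = numdiff.hessian(lambda th: loglik_independence(th, cdata), theta_hat) \
        if compute_hessian else np.full((6, 6), np.nan)
    return FrailtyFit(theta_hat=theta_hat, natural=natural, loglik_I=ll,
                      hessian=hess, converged=converged,
                      grad_norm=interior_grad, boundary=boundary,
                      start_points=record, data=data, cdata=cdata)
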