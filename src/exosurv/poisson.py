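"""Episode splitting and the piecewise-exponential (Poisson) hazard fit.

Because each granule contributes at most one event and the hazard is
piecewise constant, the time-to-event log-likelihood

    sum_ij [ d_ij log mu(t_ij | X) - M(t_ij | X) ]

coincides exactly with a Poisson log-likelihood on the episode-split table
(one row per granule x segment class, event count and exposure time), with
log rate ``alpha_k + beta_k X``.  The fit therefore goes through an ordinary
Poisson GLM with a log-exposure offset; naive and cluster-robust (sandwich)
covariances are both reported, the clusters being cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .adjust import SandwichResult, sandwich_variance
from .model import EventDataset, PoissonParams

PARAM_NAMES = ("a0", "a1", "a2", "b0", "b1", "b2")


class NonIdentifiableError(RuntimeError):
    """A free rate parameter has no events in the stratum that identifies it."""


def episode_split(dataset: EventDataset) -> pd.DataFrame:
    """Cut each granule's follow-up at the segment boundaries.

    Returns a long-format table with columns cell_id, granule_id, k (segment
    class), X, exposure (seconds spent in that class before t_ij) and events
    (the event indicator attributed to the class containing t_ij).
    Contiguous spells of equal class are merged; this aggregation leaves the
    Poisson likelihood unchanged.  Rows with zero exposure and no event are
    dropped.
    """
    df = dataset.table
    protocol = dataset.protocol
    if (df["time"] <= 0).any():
        raise ValueError("records must have positive observation time")
    expo = protocol.class_exposures(df["time"].to_numpy())  # (n, 3)
    t_ev = np.minimum(df["time"].to_numpy(),
                      np.nextafter(protocol.observation_end, 0.0))
    event_class = np.array([int(protocol.segment_of(ti)) for ti in t_ev])
    rows = []
    for k in range(3):
        events = ((df["event"].to_numpy() == 1) & (event_class == k)).astype(int)
        rows.append(pd.DataFrame({
            "cell_id": df["cell_id"], "granule_id": df["granule_id"],
            "k": k, "X": df["diabetic"], "exposure": expo[:, k],
            "events": events,
        }))
    table = pd.concat(rows, ignore_index=True)
    keep = (table["exposure"] > 0) | (table["events"] > 0)
    return table[keep].reset_index(drop=True)


def poisson_loglik(table: pd.DataFrame, params: PoissonParams) -> float:
    """Poisson-form log-likelihood sum(events * log rate - rate * exposure);
    identical to the survival-form log-likelihood of the piecewise model."""
    log_rate = np.array([params.log_rate(int(k), int(x))
                         for k, x in zip(table["k"], table["X"])])
    return float(np.sum(table["events"] * log_rate
                        - np.exp(log_rate) * table["exposure"]))


def _design(table: pd.DataFrame, constraints: tuple[str, ...]):
    """Design matrix mapping free parameters to log rates.

    ``constraints`` may contain ``"a0=a1"`` (shared first/later pulse rate)
    and ``"b0=0"``, ``"b1=0"``, ``"b2=0"`` (no covariate effect in a
    branch).  Returns (X matrix, free parameter names, full 6-vector
    embedding matrix A with log-rate-vector = A @ free)."""
    k = table["k"].to_numpy()
    x = table["X"].to_numpy()
    cols: dict[str, np.ndarray] = {}
    if "a0=a1" in constraints:
        cols["a01"] = ((k == 0) | (k == 1)).astype(float)
    else:
        cols["a0"] = (k == 0).astype(float)
        cols["a1"] = (k == 1).astype(float)
    cols["a2"] = (k == 2).astype(float)
    for kk in range(3):
        if f"b{kk}=0" not in constraints:
            cols[f"b{kk}"] = ((k == kk) * x).astype(float)
    # a class absent from the table contributes an all-zero column; its rate
    # is unestimable and the column is dropped (the full 6-vector keeps nan)
    names = [n for n in cols if np.any(cols[n] != 0)]
    mat = np.column_stack([cols[n] for n in names])
    embed = np.zeros((6, len(names)))
    for j, n in enumerate(names):
        if n == "a01":
            embed[0, j] = embed[1, j] = 1.0
        else:
            embed[PARAM_NAMES.index(n), j] = 1.0
    return mat, names, embed


@dataclass
class PoissonFit:
    """MLE of the piecewise-constant hazard with naive and cluster-robust
    covariance (on the free-parameter scale)."""

    params: PoissonParams
    free_names: list[str]
    free_values: np.ndarray
    loglik: float
    naive_vcov: np.ndarray
    robust: SandwichResult
    n_clusters: int
    converged: bool
    constraints: tuple[str, ...]

    @property
    def robust_vcov(self) -> np.ndarray:
        return self.robust.R

    def contrast(self, c: np.ndarray) -> tuple[float, float, float]:
        """Estimate, robust SE and naive SE of the linear contrast c'theta."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.free_values)
        return (est, float(np.sqrt(c @ self.robust.R @ c)),
                float(np.sqrt(c @ self.naive_vcov @ c)))


def fit_piecewise_exponential(table: pd.DataFrame,
                              constraints: tuple[str, ...] = ()) -> PoissonFit:
    """Maximum-likelihood fit of the episode-split table via Poisson GLM.

    Supports constrained refits for nested comparisons (see ``_design``).
    Raises :class:`NonIdentifiableError` when a stratum required by a free
    parameter contains no events (its MLE would diverge to -inf).
    """
    if table["events"].sum() < 1:
        raise NonIdentifiableError("no events in the data")
    mat, names, embed = _design(table, constraints)
    # each distinct design row is a stratum with its own fitted rate; a
    # stratum with exposure but no events sends that rate to zero and the
    # corresponding log-rate combination to -inf
    uniq, inv = np.unique(mat, axis=0, return_inverse=True)
    ev = np.bincount(inv, weights=table["events"].to_numpy())
    expo_tot = np.bincount(inv, weights=table["exposure"].to_numpy())
    starved = (ev == 0) & (expo_tot > 0)
    if starved.any():
        bad = [dict(zip(names, uniq[i])) for i in np.nonzero(starved)[0]]
        raise NonIdentifiableError(
            f"stratum/strata with exposure but no events: {bad}")

    offset = np.log(table["exposure"].to_numpy())
    glm = sm.GLM(table["events"].to_numpy(), mat,
                 family=sm.families.Poisson(), offset=offset)
    res = glm.fit()
    free = np.asarray(res.params)
    full = embed @ free
    for k in range(3):  # alpha of a class absent from the table: unestimable
        if not embed[k].any():
            full[k] = np.nan
        if not embed[3 + k].any() and f"b{k}=0" not in constraints:
            full[3 + k] = np.nan
    params = PoissonParams(alpha=tuple(full[:3]), beta=tuple(full[3:]))
    naive = np.asarray(res.cov_params())

    # cluster-robust sandwich: analytic per-cluster scores of the Poisson
    # log-likelihood, U_j = sum_{rows in j} x_r (d_r - mu_r)
    mu = np.exp(mat @ free + offset)
    resid = table["events"].to_numpy() - mu
    codes, _ = pd.factorize(table["cell_id"])
    J = codes.max() + 1
    scores = np.zeros((J, len(names)))
    np.add.at(scores, codes, mat * resid[:, None])
    H = -(mat.T * mu) @ mat  # observed information (negative Hessian) sign: Hessian
    robust = sandwich_variance(H, scores)
    return PoissonFit(params=params, free_names=names, free_values=free,
                      loglik=poisson_loglik(table, params), naive_vcov=naive,
                      robust=robust, n_clusters=int(J),
                      converged=bool(res.converged), constraints=constraints)


def wald_interval(estimate: float, se: float, level: float = 0.95,
                  transform=None) -> tuple[float, float]:
    """Wald interval on the working scale, optionally back-transformed
    through a monotone map (e.g. ``np.exp`` for log rates)."""
    if se < 0:
        raise ValueError("se must be nonnegative")
    z = stats.norm.ppf(1 - (1 - level) / 2)
    lo, hi = estimate - z * se, estimate + z * se
    if transform is not None:
        lo, hi = transform(lo), transform(hi)
    return float(lo), float(hi)


def wald_pvalue(estimate: float, se: float, df: int | None = None,
                null: float = 0.0) -> float:
    """Two-sided Wald p-value; a t reference with ``df`` degrees of freedom
    when given (cluster-corrected tests use df = J - 1), else normal."""
    if se == 0:
        return 0.0 if estimate != null else 1.0
    z = (estimate - null) / se
    if df is not None:
        return float(2 * stats.t.sf(abs(z), df))
    return float(2 * stats.norm.sf(abs(z)))
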