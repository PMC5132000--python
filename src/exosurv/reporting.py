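"""Model-free Kaplan-Meier estimation, curve overlays and results tables.

The KM cumulative incidence is the model-free benchmark the frailty model is
judged against: on a well-specified fit the model-based marginal incidence
curve should track the KM steps.  Tables mirror the layout conventional for
this analysis: one row per natural-scale parameter with its 95% CI, the
cluster-robust p-value and the naive (independence) p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from . import adjust
from .frailty import FrailtyFit, params_from_theta
from .model import EventDataset, SurvivalCurve, incidence_components
from .poisson import PoissonFit, wald_interval, wald_pvalue


@dataclass
class KMEstimate:
    """Product-limit survival estimate with Greenwood log-log bands."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def survival_curve(self) -> SurvivalCurve:
        return SurvivalCurve(self.event_times, self.survival, "survival", "km")

    def incidence_curve(self) -> SurvivalCurve:
        return SurvivalCurve(self.event_times, 1 - self.survival,
                             "incidence", "km")

    def survival_at(self, t) -> np.ndarray:
        """Right-continuous step interpolation of the survival estimate."""
        idx = np.searchsorted(self.event_times, np.asarray(t, float),
                              side="right") - 1
        vals = np.concatenate([[1.0], self.survival])
        return vals[idx + 1]


def kaplan_meier(dataset: EventDataset, stratum: int | None = None,
                 level: float = 0.95) -> KMEstimate:
    """Kaplan-Meier estimate, optionally within one covariate stratum.

    Units censored at an event time are counted as still at risk at that
    time (censoring-after-events convention).
    """
    df = dataset.table
    if stratum is not None:
        df = df[df["diabetic"] == stratum]
        if len(df) == 0:
            raise ValueError(f"empty stratum diabetic={stratum}")
    kmf = KaplanMeierFitter(alpha=1 - level)
    kmf.fit(df["time"], df["event"])
    tbl = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 \
        else kmf.event_table
    observed = tbl[tbl["observed"] > 0]
    times = observed.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy()
    ci = kmf.confidence_interval_survival_function_
    lo = np.interp(times, ci.index.to_numpy(), ci.iloc[:, 0].to_numpy())
    hi = np.interp(times, ci.index.to_numpy(), ci.iloc[:, 1].to_numpy())
    return KMEstimate(event_times=times,
                      at_risk=observed["at_risk"].to_numpy(),
                      events=observed["observed"].to_numpy(),
                      survival=surv, ci_lower=lo, ci_upper=hi)


def curve_frame(dataset: EventDataset, fit: FrailtyFit,
                grid: np.ndarray | None = None) -> pd.DataFrame:
    """Long-format overlay of KM and model curves for both strata."""
    if grid is None:
        grid = np.linspace(0, dataset.protocol.observation_end, 501)
    frames = []
    for X in sorted(dataset.table["diabetic"].unique()):
        comp = incidence_components(grid, X, fit.natural, dataset.protocol)
        for name, curve in comp.items():
            frames.append(pd.DataFrame({
                "time": curve.times, "value": curve.values,
                "component": name, "stratum": X}))
        km = kaplan_meier(dataset, stratum=X)
        frames.append(pd.DataFrame({
            "time": km.event_times, "value": 1 - km.survival,
            "component": "km", "stratum": X}))
    return pd.concat(frames, ignore_index=True)


def poisson_results_table(fit: PoissonFit, level: float = 0.95) -> pd.DataFrame:
    """Six-row report (rho0, rho1, rho2, beta0, beta1, beta2).

    Rate rows back-transform log-scale Wald intervals; the rho0 and rho2
    p-values test the contrasts alpha0 = alpha1 and alpha2 = alpha1, the
    beta rows test beta_k = 0.  Robust p-values use a t reference with
    J - 1 degrees of freedom; naive p-values ignore clustering.
    """
    if not fit.converged:
        raise RuntimeError("fit did not converge; refusing to tabulate")
    df_t = fit.n_clusters - 1
    names = fit.free_names
    rows = []
    contrast_null = {"a0": "a1", "a2": "a1"}
    for name in names:
        j = names.index(name)
        est = fit.free_values[j]
        se_r = float(np.sqrt(fit.robust.R[j, j]))
        se_n = float(np.sqrt(fit.naive_vcov[j, j]))
        is_rate = name.startswith("a")
        lo, hi = wald_interval(est, se_r, level,
                               transform=np.exp if is_rate else None)
        p_r = p_n = np.nan
        if is_rate and contrast_null.get(name) in names:
            c = np.zeros(len(names))
            c[j], c[names.index(contrast_null[name])] = 1.0, -1.0
            c_est, c_se_r, c_se_n = fit.contrast(c)
            p_r = wald_pvalue(c_est, c_se_r, df=df_t)
            p_n = wald_pvalue(c_est, c_se_n)
        elif not is_rate:
            p_r = wald_pvalue(est, se_r, df=df_t)
            p_n = wald_pvalue(est, se_n)
        label = name.replace("a", "rho") if is_rate else name.replace("b", "beta")
        rows.append({
            "parameter": label,
            "estimate": float(np.exp(est)) if is_rate else float(est),
            "ci_lower": lo, "ci_upper": hi,
            "p_robust": p_r, "p_naive": p_n,
        })
    return pd.DataFrame(rows)


NATURAL_TRANSFORMS = {
    "rho1": (0, np.exp), "rho2": (1, np.exp), "beta2": (2, lambda x: x),
    "eta": (3, np.exp),
    "pi0": (4, lambda x: x ** 2), "pi1": (5, lambda x: x ** 2),
}


def frailty_results_table(fit: FrailtyFit, adj: adjust.AdjustedLikelihood,
                          naive_tests: bool = True,
                          level: float = 0.95) -> pd.DataFrame:
    """Six-row frailty report (rho1, rho2, beta2, eta, pi0, pi1).

    CIs are profile-likelihood intervals from the adjusted log-likelihood,
    back-transformed to the natural scale.  p-values are adjusted LRTs: the
    rho2 row tests rho1 = rho2 (a tie constraint), beta2 tests beta2 = 0,
    eta tests eta = 1 and the pi rows test the boundary nulls pi_X = 0 with
    the half-half chi-square mixture reference.  ``naive_tests`` adds the
    corresponding unadjusted (independence) LRT p-values.
    """
    if not fit.converged:
        raise RuntimeError("fit did not converge; refusing to tabulate")
    from .frailty import DEFAULT_BOUNDS, fit_frailty
    rows = []
    tests: dict[str, dict] = {
        "rho2": {"ties": [(0, 1)], "boundary": False},
        "beta2": {"fixed": {2: 0.0}, "boundary": False},
        "eta": {"fixed": {3: 0.0}, "boundary": False},
        "pi0": {"fixed": {4: 0.0}, "boundary": True},
        "pi1": {"fixed": {5: 0.0}, "boundary": True},
    }
    for label, (idx, transform) in NATURAL_TRANSFORMS.items():
        lo, hi = adjust.profile_ci(adj, idx, level, bounds=DEFAULT_BOUNDS)
        p_a = p_n = np.nan
        spec = tests.get(label)
        if spec is not None:
            res = adjust.lrt_adjusted(adj, fixed=spec.get("fixed"),
                                      ties=spec.get("ties"),
                                      boundary=spec["boundary"],
                                      bounds=DEFAULT_BOUNDS)
            p_a = res.pvalue
            if naive_tests:
                if "ties" in spec:
                    ll_c = _tied_refit(fit)
                else:
                    cfit = fit_frailty(fit.data, frozen=spec["fixed"],
                                       compute_hessian=False)
                    ll_c = cfit.loglik_I
                stat_n = max(0.0, 2 * (fit.loglik_I - ll_c))
                p_n = adjust.mixture_pvalue(stat_n, spec["boundary"])
        rows.append({
            "parameter": label,
            "estimate": float(transform(fit.theta_hat[idx])),
            "ci_lower": float(transform(lo)), "ci_upper": float(transform(hi)),
            "p_adjusted": p_a, "p_naive": p_n,
        })
    return pd.DataFrame(rows)


def _tied_refit(fit: FrailtyFit) -> float:
    """Constrained independence log-likelihood under rho1 = rho2."""
    from scipy import optimize

    from .frailty import DEFAULT_BOUNDS, loglik_independence
    data = fit.data.collapse()
    idx = [0, 2, 3, 4, 5]  # alpha2 tied to alpha1

    def neg(free):
        th = np.empty(6)
        th[idx] = free
        th[1] = th[0]
        return -loglik_independence(th, data)

    res = optimize.minimize(neg, fit.theta_hat[idx], method="L-BFGS-B",
                            bounds=[DEFAULT_BOUNDS[k] for k in idx],
                            options={"maxiter": 500, "ftol": 1e-12})
    return float(-res.fun)


def docked_granule_count(capacitance_pf: float = 10.0,
                         specific_capacitance_ff_per_um2: float = 10.0,
                         density_per_um2: float = 0.8) -> float:
    """Docked granules per cell from membrane capacitance.

    Membrane area = capacitance / specific capacitance; docked count =
    area x docking density.  With the defaults (10 pF cell, 10 fF/um^2,
    0.8 granules/um^2) this gives ~800 granules per cell.
    """
    area_um2 = capacitance_pf * 1000.0 / specific_capacitance_ff_per_um2
    return area_um2 * density_per_um2


def irp_granule_count(pi: float, docked: float = 800.0) -> float:
    """IRP size in granules: docked count times the IRP fraction pi_X."""
    return docked * pi
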