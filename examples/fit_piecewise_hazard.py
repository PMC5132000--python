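"""Fit the three-branch piecewise-constant hazard (Poisson formulation).

The hazard of exocytosis takes one constant rate during the first K+ pulse,
another during later pulses and a third between pulses, each multiplied by
exp(beta_k) in diabetic cells.  Episode splitting turns each granule's
follow-up into one exposure row per segment class, after which the fit is an
ordinary Poisson regression with a log-exposure offset.  Standard errors are
reported both naively (granules independent) and cluster-robust (granules
correlated within a cell).
"""

import exosurv as es

design = es.SimulationDesign(n_cells_healthy=25, n_cells_diabetic=25,
                             granules_per_cell=150,
                             cell_heterogeneity_variance=0.5, seed=3)
dataset = es.simulate_dataset(design)

table = es.episode_split(dataset)
fit = es.fit_piecewise_exponential(table)
report = es.poisson_results_table(fit)

print(report.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print()
print("rho0/rho1/rho2 are exocytosis rates (s^-1) in the first pulse, later")
print("pulses and rest intervals; beta_k are log hazard ratios of diabetes.")
print("p_robust uses the cluster sandwich variance (t, J-1 df); p_naive")
print("ignores the within-cell correlation and is typically too small.")
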