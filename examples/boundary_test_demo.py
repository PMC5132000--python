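"""Test whether diabetic cells have any immediately releasable pool.

The null pi1 = 0 sits on the boundary of the parameter space, so the
likelihood-ratio statistic is referred to the (chi2_0 + chi2_1)/2 mixture
(a one-sided test).  The demonstration simulates a study in which the
diabetic IRP truly is absent but cells share an unmodelled responsiveness
factor: the naive independence LRT treats the correlated granules as
independent evidence, while the cluster-adjusted LRT does not.
"""

import exosurv as es

truth = es.FrailtyParams(alpha1=-6.7510, alpha2=-8.8740, beta2=1.43,
                         eta=499.5, pi0=0.026, pi1=0.0)  # no diabetic IRP
design = es.SimulationDesign(n_cells_healthy=20, n_cells_diabetic=20,
                             granules_per_cell=150, truth=truth,
                             cell_heterogeneity_variance=0.5, seed=10_010)
dataset = es.simulate_dataset(design)

fit = es.fit_frailty(dataset)
print(f"estimated diabetic IRP fraction pi1 = {fit.natural.pi1:.4f} "
      f"(truth: 0)")

adjusted = es.boundary_pi_test(fit, which=1)
naive = es.boundary_pi_test(fit, which=1, naive=True)
print(f"adjusted LRT: Lambda_A = {adjusted.stat:.3f}, p = {adjusted.pvalue:.3f}")
print(f"naive LRT:    Lambda_I = {naive.stat:.3f}, p = {naive.pvalue:.3f}")
print()
print("In any single study the two statistics can be close; across repeated")
print("studies with correlated granules the naive test rejects a true null")
print("too often, while the adjusted test holds (approximately) nominal size.")
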