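# exosurv

Time-to-event analysis of single-granule exocytosis under pulsed
depolarization: piecewise-constant hazard regression, a discrete
immediately-releasable-pool (IRP) frailty model, and cluster-robust
adjusted-likelihood inference.

## The problem

TIRF microscopy can follow individual insulin-containing secretory granules
at the plasma membrane of a pancreatic β-cell while trains of depolarizing
K⁺ pulses trigger exocytosis. Each granule yields a classic survival-analysis
observation: either the time of its fusion event or a right-censoring time
when the recording ends. Two features make naive analysis wrong:

* **Hidden heterogeneity.** A small subpopulation of docked granules — the
  immediately releasable pool — fuses orders of magnitude faster than the
  rest, but membership is invisible in the images.
* **Clustering.** Granules of one cell are correlated (some cells are
  inherently highly responding), so treating them as independent
  observations makes standard errors far too small.

`exosurv` is for experimentalists and biostatisticians who want rates of
exocytosis, IRP sizes and covariate effects (here: healthy vs diabetic
donor) with inference that respects both features.

## The models

Time runs from the onset of the first pulse; the default protocol is ten
1-s pulses at 10-s spacing with censoring at 100 s. With X ∈ {0, 1} the
diabetic indicator, the **piecewise Poisson model** sets

    μ(t|X) = ρ0 e^{β0 X}   first pulse,   0 ≤ t < 1
             ρ1 e^{β1 X}   later pulses,  s ≤ t < s+1, s = 10, 20, …
             ρ2 e^{β2 X}   between pulses

and is fitted as a Poisson GLM on the episode-split exposure table — the
two likelihoods coincide exactly for single-event subjects.

The **frailty model** instead keeps one pulse rate ρ1 (no first-pulse
exception, β1 = 0) and gives each granule a two-point frailty Z:

    μ(t|X,Z) = Z μ0(t|X),   P(Z = η | X) = π_X,   P(Z = 1 | X) = 1 − π_X,

so π_X is the IRP fraction and η the IRP rate multiplier. Marginally
S(t|X) = π_X e^{−η M0(t|X)} + (1 − π_X) e^{−M0(t|X)} with M0 the cumulative
baseline hazard. The frailty is integrated out to form the working
independence log-likelihood ℓ_I, maximized on the working scale
θ = (α1, α2, β2, log η, √π0, √π1).

Clustering is handled after the fit: per-cell score contributions give the
sandwich variance R = Ĥ⁻¹V̂Ĥ⁻¹, and the curvature-adjusted log-likelihood
ℓ_A(θ) = ℓ_I(C(θ − θ̂) + θ̂), with C built from spectral square roots of −Ĥ
and R⁻¹, keeps the same maximizer but acquires curvature −R⁻¹. Likelihood
ratio tests and profile confidence intervals computed from ℓ_A are valid
under within-cell correlation; nulls on the parameter boundary (π_X = 0)
use the (χ²₀ + χ²₁)/2 mixture reference.

A seeded synthetic-data generator draws event times by exact inversion of
the piecewise cumulative hazard, with optional gamma-distributed cell-level
factors that induce the within-cell correlation the fitted model omits.

## Worked example

`python examples/fit_frailty_model.py` simulates 50 cells × 150 granules at
the reference parameter values and refits them:

```
parameter  estimate  ci_lower  ci_upper  p_adjusted   p_naive
     rho1  0.001083 0.0008664  0.001338         NaN       NaN
     rho2 0.0001681 0.0001342 0.0002064   8.741e-26 1.472e-43
    beta2     1.235     1.008     1.472   3.376e-29 5.784e-18
      eta     510.6     403.6     642.3   5.061e-41 1.001e-41
      pi0   0.02214   0.01795   0.02679   6.738e-23 1.588e-33
      pi1   0.01108  0.006516   0.01679   3.794e-13 3.062e-14

implied IRP size for an 800-granule healthy cell: 17.7 granules
```

Granules fuse at ~0.0011 s⁻¹ during pulses; between pulses the healthy rate
drops ~6-fold and diabetes raises it e^1.235 ≈ 3.4-fold; IRP granules fuse
~511× faster; about 2.2% of healthy-cell granules (≈18 of ~800 docked) are
immediately releasable, half that in diabetic cells. The `p_adjusted`
column comes from cluster-adjusted likelihood-ratio tests (boundary-mixture
for the π rows); `p_naive` ignores clustering. Other examples:
`simulate_events.py` (write an event CSV + protocol + truth sidecar),
`fit_piecewise_hazard.py` (three-branch Poisson table) and
`boundary_test_demo.py` (adjusted vs naive test of π1 = 0).

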