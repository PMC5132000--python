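# Methods

## Data model and time axis

One observation per granule: `(cell_id, granule_id, time, event, diabetic)`.
Time is seconds from the onset of the first depolarizing pulse. The
stimulation protocol — pulse onsets, pulse duration, observation end — is a
separate configuration object, never inferred from the data; the default is
ten 1-s pulses at 0, 10, …, 90 s with administrative censoring at 100 s.
Pulse intervals are half-open `[s, s+1)`, so an event at exactly t = 1.0 s
falls in the rest interval. Censored rows must carry `time ==
observation_end` (a validation warning flags anything else); events at
exactly the observation end are accepted as observed and attributed to the
segment just before the endpoint. The diabetic covariate is cell-level and
must be constant within a cluster. All rates are per second.

## Piecewise-exponential (Poisson) fit

Follow-up is cut at every segment boundary and aggregated by segment class
(first pulse / later pulses / between), which leaves the likelihood
unchanged; with at most one event per granule the Poisson log-likelihood on
that table equals the time-to-event log-likelihood exactly, a property the
test suite asserts to 1e-10. The fit itself is a Poisson GLM with
log-exposure offset (statsmodels); constrained refits (`a0=a1`, `bk=0`)
support nested comparisons, and the rate contrasts ρ0 = ρ1 and ρ2 = ρ1 are
tested as linear contrasts of the log rates. A stratum that carries
exposure but no events makes its log-rate diverge; the fit raises a
`NonIdentifiableError` rather than returning silently.

Cluster-robust variance uses the score-based sandwich Ĥ⁻¹V̂Ĥ⁻¹ with
analytic per-cell Poisson scores; Wald p-values use a t reference with
J − 1 degrees of freedom (J = number of cells), a documented convention —
the appropriate small-sample df for cluster-corrected t-tests is not
settled, and J − 1 is the conservative standard choice. Naive p-values use
the normal reference. The statsmodels cluster covariance (without
small-sample correction) serves as an independent cross-check in the tests.

## Frailty likelihood

The marginal per-granule contribution after integrating the two-point
frailty is

    l_ij = d log μ0(t|X) + log( π_X η^d e^{−η M0(t|X)} + (1−π_X) e^{−M0(t|X)} )

computed with log-sum-exp across the two branches: with η ≈ 500 and M0 of
order 1, e^{−ηM0} underflows any naive evaluation. The likelihood depends
on a granule only through (pulse exposure, rest exposure, event indicator,
event segment, covariate), so identical granules are collapsed with
multiplicity weights before optimization — an exact rewrite that makes
large simulations cheap. Per-cluster score sums keep the uncollapsed
cluster structure.

### Working scale

θ = (α1, α2, β2, log η, √π0, √π1). Logs for the rates and η are standard.
For the IRP probabilities the square root — not the logit — is used, a
deliberate design choice with three reasons: (i) the boundary null π = 0
must sit at a *finite* working value for the curvature-adjusted likelihood
to act on it — on the logit scale the null is at −∞ where the likelihood is
flat and the adjusted LR statistic degenerates to the unadjusted one;
(ii) π = θ² keeps the probability nonnegative under any finite-difference
excursion, so numerical gradients and Hessians never leave the domain;
(iii) the square root is the variance-stabilizing transform for small
probabilities, giving near-quadratic, symmetric log-likelihoods. Affine
images of working points under the adjustment map can overshoot π = 1
slightly; the likelihood clips π at 1 (extended-value convention).

### Optimization

L-BFGS-B within the box α ∈ (−25, 5), β2 ∈ (−10, 10), log η ∈ (−5, 12),
√π ∈ [0, 1], from a 9-point starting grid: the closed-form no-frailty MLE
of (α1, α2, β2) crossed with η ∈ {10, 100, 1000} and π ∈ {0.005, 0.02,
0.1}. Relative objective tolerance 1e-12; the fit records every start and
its objective, checks the gradient sup-norm at the optimum (1e-5 relative
to |ℓ|, bound-active coordinates excluded), flags boundary solutions
(π̂ within 1e-6 of 0 or 1, or any coordinate at its box edge), and raises
if no start converges. η > 1 is not enforced; fits with η̂ ≤ 1 surface
through the recorded parameters.

## Cluster-adjusted inference

Per-cluster scores are numerical gradients (central differences with one
Richardson step; steps scale as ε^{1/3} per coordinate, ε^{1/4} for
Hessians) of the summed cluster contributions. The sandwich is
R = Ĥ⁻¹V̂Ĥ⁻¹ with V̂ = Σ U_j U_jᵀ; a condition number above 1e12 on Ĥ is an
error. The adjusted log-likelihood is ℓ_A(θ) = ℓ_I(C(θ − θ̂) + θ̂) with
C = N⁻¹N_A, where N and N_A are symmetric (spectral) square roots of −Ĥ
and R⁻¹ respectively — the positive-definite forms of the observed
information and inverse sandwich; taking roots of the negated matrices is
the only real-valued reading of the construction and leaves C unchanged.
The defining properties — same maximizer and value, curvature −R⁻¹ — are
verified numerically in the tests (1e-4 relative).

Likelihood-ratio tests constrain coordinates (frozen values) or ties
(θ_a = θ_b, used for ρ1 = ρ2) inside the same quasi-Newton maximizer.
Interior nulls use χ²₁; boundary nulls (π_X = 0) use the (χ²₀ + χ²₁)/2
mixture, i.e. p = ½P(χ²₁ ≥ Λ) for Λ > 0 and p = 1 at Λ = 0. When the
unconstrained estimate itself sits on the boundary the statistic is zero by
construction and the curvature adjustment is skipped — the observed
information is singular in that direction and the answer (no rejection)
does not depend on it. A negative statistic beyond −1e-4 signals a failed
unconstrained optimum and raises. The η row of the results table tests
η = 1 against χ²₁; at that null the π parameters are unidentified, so the
reference distribution is approximate — the test is reported for
completeness, as is conventional, and should be read qualitatively.

Profile confidence intervals bracket the deviance 2(ℓ_A(θ̂) − profile ℓ_A)
against the χ²₁ quantile and solve by Brent root finding with warm-started
nuisance maximizations. If the deviance never reaches the quantile before
the working-scale box edge (typically √π at 0 for a barely identified IRP),
the box edge is returned for that side with a warning that the interval is
effectively one-sided.

## Synthetic-data generator

The generator emulates the reference study design: 11 healthy + 8 diabetic
cells (19 clusters), ten 1-s pulses, censoring at 100 s, granule-level
two-point frailty, and within-cell correlation via a cell factor w with
mean 1 and variance v multiplying every hazard in the cell. Defaults:
100 granules per cell (the study does not report per-cell counts; a TIRF
footprint shows on the order of 10² docked granules), v = 0.5, and the
reference frailty estimates as ground truth. w is gamma-distributed — the
standard shared-frailty convention; any mean-1 nonnegative law would serve.
Event times come from exact segment-by-segment inversion of
multiplier × M0(t) = −log u, so the sampler shares no code with the fitted
likelihood and serves as an independent check of it. Draws consume the
generator in a fixed order (cells healthy-first; per cell: w, then frailty
uniforms, then time uniforms), making seeds portable across designs.

The cell factor is deliberately absent from the fitted model: it reproduces
the real situation where clustering is unmodelled and handled purely by
robust variance. Consequently passing tests show that the *inference*
machinery is robust to this correlation — they do not show that the
two-point frailty captures every form of real heterogeneity (continuous
release propensities, time-varying Ca²⁺ coupling, spatial structure are all
outside the generator and the model).

## Validation problem sizes

The test suite checks the sampler against the closed-form mixture survival
at 10⁵ granules per stratum (sup-distance < 0.01); parameter recovery and
95% profile-CI coverage over 20 replicates of 200 cells × 150 granules at
the reference truth with v = 0 (median relative error < 15% per parameter,
coverage ≥ 80%); and the size of the boundary-mixture LRT of π1 = 0 over
200 replicates of 40 cells × 150 granules with v = 0.5 — the adjusted test
within [0.02, 0.09] at nominal 0.05 and the naive independence LRT above
it. The calibration design uses 40 clusters, about twice the reference
study, so that the large-J asymptotics of the adjustment have taken hold
while per-cell granule counts stay at realistic TIRF scale.

## Known limitations

* Covariate effects enter proportionally within segments; no left
  truncation, competing risks or time-varying covariates.
* The adjustment assumes enough clusters for Ĥ and R to be well
  conditioned; with very few cells (< ~10) `build_adjustment` may
  legitimately refuse.
* The uniform multiplicative cell factor leaves the IRP-fraction direction
  only mildly correlated within cells, so the naive-vs-adjusted size gap in
  the calibration study is smaller than what strongly IRP-heterogeneous
  cells would produce.
* Granule counts per cell in real recordings vary; the generator's default
  is a stated convention, recorded in the truth sidecar, not a measured
  fact.
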