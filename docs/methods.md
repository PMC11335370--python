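# Methods

## Kinetic model

The two-compartment system couples tracer availability α(t) to the
protein's relative isotope abundance β(t):

dα/dt = λ f(t) − k_c α,  dβ/dt = k_c (α − β),  α(0) = β(0) = 0,

with f(t) = 1 on [0, 9] hours (boundary inclusive) and 0 after. Both
compartments are dimensionless ratios; λ and k_c are rates in h⁻¹. Under
sustained infusion both α and β relax to λ/k_c, so λ acts as a scale
parameter and k_c as the shape/half-life parameter (t½ = ln 2/k_c).

Because the system is linear, it has an exact piecewise solution
(during infusion: α = (λ/k_c)(1 − e^(−k_c t)),
β = (λ/k_c)(1 − e^(−k_c t)) − λ t e^(−k_c t); after infusion both decay
as e^(−k_c τ) with a secular k_c α(T) τ term in β). The closed form was
verified two ways before adoption: finite-difference residuals of the
stated formulas inserted into the ODEs vanish, and a Radau (implicit
5th-order Runge–Kutta, stiff-capable) integration split at the infusion
discontinuity agrees to ~1e-12 across λ, k_c ∈ [1e-3, 10]. The closed
form is the production path for all fitting and simulation — it is exact
and orders of magnitude faster — while `solve_ode` remains as an
independent numerical route; their equivalence is a standing test.
Model evaluation at observation times is always direct closed-form
evaluation, never interpolation.

## QNB: weighted least squares with balanced bootstrap

RIA = PH/(PL+PH). Observations are weighted proportionally to PH
(stronger heavy-channel signal → more precise ratio); weights are
normalized to mean 1 within each (patient, protein) series so that the
residual variance σ² has a stable interpretation and all results are
invariant to rescaling raw intensities. Rows with PH = 0 receive zero
weight and are excluded; rows with PL+PH = 0 have no defined ratio and
are dropped at read time.

The objective Σ wᵢ (RIAᵢ − (β(tᵢ) − s))² is minimized by BFGS over
(ln λ, ln k_c, s); the log parameterization enforces positivity without
constraints. The surface has flat plateaus (large k_c flattens the curve
and s absorbs the mean), so if the optimum explains less variance than a
constant fit, the optimizer restarts from the best node of a coarse
log-space grid; clean fits never trigger the restart.

Outlier calling is a single pass: fit, flag, refit. An observation is
flagged when its vertical residual to the shifted fitted curve exceeds
half the range (max − min) of β(t) evaluated densely over the observed
time span — the range of the curve itself, not of the shifted curve —
and all time-0 rows are always flagged, since no tracer has been
incorporated at baseline. If every observation is flagged the series is
rejected as unusable.

Confidence intervals are percentile intervals from a nonparametric
balanced bootstrap with 100 resamples: the index set is concatenated 100
times, permuted, and split, so every observation appears exactly 100
times across resamples. Resamples with fewer than three distinct times
(or failed refits) fall back to the point estimate, and the interval is
widened if needed to contain the point estimate. Bootstrap resampling
treats observations as independent (replicate pairing is not preserved).
Measured over 200 independent plasma-like simulations, the CI95 for k_c
covers the generating value ~93% of the time.

## Individual Bayesian model

Priors: ln λ ~ N(μ_lλ, σ²_lλ), ln k_c ~ N(μ_lkc, σ²_lkc),
s ~ N(0, σ_s²), σ⁻² ~ Gamma(0.001, 0.001) (shape/rate; the standard
vague precision prior). The log-normal prior constants are learned as
sample means/variances of ln λ and ln k_c over a large reference
collection of QNB fits (`learn_prior_from_fits`); σ_s² is matrix-
specific: 1e-3 for plasma, 1/500 for the noisier CSF. Likelihood:
RIAᵢ ~ N(β(tᵢ) − s, σ²/wᵢ) with outliers already removed by the QNB
rule (a heavy-tailed likelihood would be the alternative; it is
deliberately out of scope).

Sampler: Metropolis-within-Gibbs. The block (ln λ, ln k_c, s) uses a
random-walk proposal whose per-coordinate scales adapt every 100
iterations toward ~30% acceptance; adaptation runs only during burn-in
and is frozen afterwards so the retained draws target the exact
posterior. σ⁻² is drawn exactly from its conjugate full conditional
Gamma(a + n/2, b + WSS/2) with WSS the weighted residual sum of squares;
this update is validated against a brute-force normalized grid density.
Chains initialize ln λ and ln k_c from their priors (or at QNB estimates
on request), s at 0 and σ² at 0.1. Defaults are 2 chains × 100 000
iterations, 50 000 burn-in. With no observations the sampler returns
prior draws, which the tests use to confirm correctness of the prior
terms.

## Population model

θ_k = (ln λ_k, ln k_c,k) ~ N₂(μ_θ, Ω) with hyper-priors
μ_θ ~ N₂(μ, Σ) and Ω⁻¹ ~ Wishart₂(R, 2). **Wishart convention**: we use
the BUGS parameterization in which Wi(R, ν) is a distribution over the
precision matrix with density ∝ |Ω⁻¹|^((ν−p−1)/2) exp(−tr(R Ω⁻¹)/2) and
expectation ν R⁻¹ — equivalently scipy's `wishart(df=ν, scale=R⁻¹)`.
Conventions differ across ecosystems; a moment test pins ours down.
Vague defaults: Σ⁻¹ = diag(1e-4), R = diag(0.175), ν = 2. The
informative mode sets μ to the average of per-patient QNB estimates and
diag(Σ⁻¹) to their reciprocal sample variances, leaving the Wishart
settings vague; it is the recommended default for heterogeneous cohorts.
σ² is shared across patients within a protein (the likelihood subscript
carries no per-patient index); shifts s_k are per-patient.

Updates per sweep: conjugate bivariate-normal draw of μ_θ; conjugate
Wishart draw of Ω⁻¹ (scale R + Σ_k (θ_k − μ_θ)(θ_k − μ_θ)ᵀ, ν + K
degrees of freedom); per-patient adaptive random-walk Metropolis for θ_k
(the likelihood is nonlinear in θ through the ODE solution, so no
conjugacy); conjugate normal draw of each s_k; conjugate gamma draw of
σ⁻². All conjugate blocks are validated against brute-force grid
densities of the joint on a tiny two-patient instance. Chains start at
s_k = 0, σ² = 0.01, and θ_k either drawn around μ (prior-draw; the
near-flat vague hyper-prior is capped at unit covariance for
initialization only) or at the QNB estimates (qnb-start, the rescue for
divergent cohorts).

Divergence detection targets the characteristic failure mode in which
ln λ grows without bound while ln k_c shrinks to compensate: a chain is
flagged when the linear trends of the two components over the inspection
window have opposite signs and each moves by more than 2 natural-log
units, or when any component exceeds |15| (e^15 h⁻¹ is far outside any
physiological rate). Thresholds are configurable; a flagged run raises
an error advising qnb-start initialization or the informative prior.

## Diagnostics

PSRF: √[((n−1)/n · W + B/n)/W] with W the mean within-chain variance and
B = n · var(chain means); identical chains give √((n−1)/n) ≈ 1. The
pass threshold defaults to 1.05 (configurable; no canonical value
exists). MCSE: batch means with batch length ⌊√n⌋ — the variance of
batch means times batch length estimates the long-run variance, so
autocorrelation inflates the MCSE relative to sd/√n, recovering the iid
value for independent draws (within Monte-Carlo error, a batch-means
estimator can sit slightly below sd/√n on finite iid samples). Per-chain
MCSEs are pooled as the root-mean-square divided by √(chains). The
adequacy rule is MCSE/SD ≤ 5%, boundary inclusive.

## Posterior-predictive summaries

Coverage regions are highest-density regions computed on the
(ln λ, ln k_c) plane, where the population model is Gaussian: a Gaussian
KDE is fitted to predictive draws, the density threshold is the quantile
of the density at the draws retaining the stated mass, and contour
polylines are traced on a grid and mapped back to (λ, k_c). Membership
is defined by density ≥ threshold, which makes nesting across levels
(95 ⊂ 99 ⊂ 99.5) automatic. Predictive draws integrate over posterior
uncertainty — sample (μ_θ, Ω) from the posterior, then θ* ~ N₂(μ_θ, Ω) —
with a plug-in mode (posterior means) available, since either reading of
"the population distribution" is defensible. Dynamics bands evaluate
β(t) for each draw (s = 0) and take pointwise equal-tailed 95% intervals
per grid time; they are pointwise, not simultaneous, so a fresh
population member's curve is expected inside the band at ~95% of times,
not at all times jointly.

## Synthetic data

The generator inverts the population model: θ_k ~ N₂(μ_θ, Ω),
s_k ~ N(0, shift_sd²), RIA ~ N(β_k(t) − s_k, σ²/w) with w ∝ synthetic PH,
then (PL, PH) pairs are reconstructed so PH/(PL+PH) reproduces the drawn
ratio exactly. PH is modeled as scale·(β(t) + floor), so early time
points carry low weight — the same rationale as PH-proportional
weighting in fitting; absolute intensities are arbitrary (only ratios
and relative weights matter). Drawn ratios below 0 (essentially only at
t = 0, where β = 0) are clipped to 0 with PH = 0; such rows are excluded
by the time-0 outlier rule and the zero-weight rule anyway.

Preset conditions:

- `plasma-like` (default): sampling every 3 h from 0 to 36 h, duplicate
  injections, RIA noise sd 0.01, shift sd 0.005, μ_θ = (ln 0.05,
  ln 0.1) — a half-life of ~7 h, typical of mid-turnover plasma
  proteins — and Ω with sd 0.2 per log-component, correlation 0.3
  (moderate inter-individual variability).
- `csf-like`: sampling to 24 h, noise sd 0.02, shift sd 0.01, faster
  turnover (k_c ≈ 0.25 h⁻¹) and a much wider Ω (sd 0.5, correlation
  0.4), emulating a heterogeneous cohort.
- `csf-aberrant`: csf-like with one patient forced 4 population sd from
  μ_θ (opposite signs in the two components), emulating a pathological
  cohort member that defeats population modeling.

What the generator does not emulate: peptide-to-peptide variation within
a protein, retention-time or integration artifacts, missing time points,
heavy-tailed outliers (available only via the optional uniform-outlier
injection), or drift in tracer enrichment. Passing recovery tests
therefore shows correctness of the estimators under the assumed noise
model, not robustness to every pathology of real MRM data — the outlier
rule and the divergence detector are the designed defenses for those.

## Problem sizes and numerical choices

The test suite runs reduced-scale chains (4k–20k iterations) chosen so
that posterior Monte-Carlo error is small relative to the tolerances
being checked; the production default and the adequacy computation in
`scripts/acceptance.py` use the full 2 × 100k/50k setting. Calibration
checks use 50 simulation replicates; coverage-region self-consistency
uses 10⁴ draws. KDE contours are traced on a 200×200 grid padded 0.8
log-units beyond the draw range. Optimizer restarts, the gamma-draw
underflow clamp (vague Gamma(0.001) draws can underflow to zero), and
the initialization cap for near-flat hyper-priors are the only numerical
guards; none alter the targeted distributions.

## Known limitations

- Percentile bootstrap CIs undercover slightly at n ≈ 24 (measured ~93%
  rather than 95%); the Bayesian credible intervals are better
  calibrated, consistent with the motivation for the Bayesian route.
- The population sampler shares one σ² per protein; per-patient
  variances would require only a small change but are deliberately not
  modeled.
- No subgroup/mixture structure: a single bivariate normal describes the
  population, so a genuinely bimodal cohort (e.g. the aberrant preset)
  is fit poorly by design.
- Divergence detection is a heuristic on linear trends; slowly mixing
  but convergent chains with short burn-in can be flagged (conservative
  direction).
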