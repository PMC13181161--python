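# Methods

## Model

`jointwiv` fits a Bayesian joint model for K longitudinal biomarkers and a
right-censored, possibly left-truncated time-to-event outcome in which the
event hazard can depend on each biomarker's *within-individual variability*
(WIV) as well as its mean.

**Longitudinal submodel (mixed-effects location-scale model).** For subject
i, biomarker k, visit time t:

    y_ik(t) ~ Normal( eta_mu_ik(t), sigma_ik(t)^2 )
    eta_mu_ik(t)      = X_mu(t)  beta_mu_k  + Z_mu(t)  b_i_mu_k
    log sigma_ik(t)   = X_sig(t) beta_sig_k + Z_sig(t) b_i_sig_k

Both the mean (location) and the log residual SD (scale) have their own
fixed and random effects; `log` is the fixed link for the scale.  The
stacked random-effect vector b_i = (b_mu_1..b_mu_K, b_sig_1..b_sig_K) is
multivariate normal with covariance Sigma = T P T, where T is the diagonal
matrix of SDs tau and P an unstructured correlation matrix, so mean-WIV
and cross-biomarker correlations are estimated parameters.  K is arbitrary
in the math layer; the shipped simulator and examples use K = 2.

**Event submodel.** A proportional-hazards model

    h_i(t) = exp( log h0(t) + w_i' gamma + eta_alpha_i(t) )

with log h0(t) a cubic B-spline (default 6 basis functions over
[0, max observed time], equally spaced knots) carrying a Bayesian P-spline
prior: an improper Gaussian on r-th order coefficient differences
(default r = 2) with smoothing weight tau_h in (0,1) and rank L - r.  The
association term eta_alpha comes in three forms:

- **LP**: sum_k alpha_mu_k eta_mu_ik(t) + alpha_sig_k log sigma_ik(t)
- **CV**: as LP but the scale enters on the SD scale, exp(log sigma_ik(t))
- **RE**: alpha' b_i (time-constant)

The subject's log-likelihood is delta_i log h_i(T_i) minus the cumulative
hazard over the at-risk window [entry_i, T_i], approximated by one
15-point Gauss–Kronrod panel mapped into the window (exact for constant
hazards; relative error < 1e-10 against the closed form for log-linear
hazards, verified in the tests).  Delayed entry is handled by integrating
from the entry time only.

**Priors.** normal(0, 10) on longitudinal fixed effects; normal(0, 2.5) on
event coefficients gamma and association coefficients alpha — the scale
used by rstanarm's joint model, which also keeps the weakly identified
association directions (a biomarker whose log-SD predictor is nearly
constant makes its alpha_sigma parameter close to unidentified) well
conditioned; half-t(3, 2.5) on each tau; LKJ(1) on P through its Cholesky
factor; Beta(1, 1) on tau_h, with an optional multiplier `tau_h_scale` for
users wanting smoothing weights above 1.  All are configurable through
`PriorConfig`.

Baseline covariates are mean-centered by default (both submodels
identically, and the event covariates too); intercepts are then reported
on the centered scale.  A `center=False` flag disables this.

## Computation

No external MCMC engine is used: the package ships its own sampler.

- **Gradients.** The joint log posterior and its gradient are hand-derived
  and fully vectorised; a fused numba kernel accelerates the common model
  structure (random intercepts, CV/LP association) and is verified against
  the pure-numpy reference path in the test suite.  The correlation
  Cholesky transform's derivatives are obtained by complex-step
  differentiation of the (cheap) transform and chained analytically into
  the likelihood.
- **Sampler.** Multinomial no-U-turn HMC with dual-averaging step-size
  adaptation (target acceptance 0.8) and Stan-style windowed diagonal
  mass-matrix adaptation.  Divergences (energy error > 1000 or non-finite
  density) are counted and reported.
- **Parameterisation.** Random effects are non-centered: b_i = T L_P z_i
  with z_i standard normal.  Because several study datasets carry strong
  per-subject information, the non-centered form mixes slowly along some
  directions; the sampler therefore interleaves three posterior-invariant
  moves between NUTS iterations (for CV/LP models): a Gibbs update
  shifting each fixed intercept against the mean of its random intercepts
  (likelihood-invariant; the shift's full conditional is Gaussian); a
  Metropolis move rescaling each tau with the innovations remapped so the
  realised b stay fixed (likelihood-free, known Jacobian); and a
  preconditioned Metropolis update of the spline-coefficient block, whose
  strong within-block correlation a diagonal metric cannot express
  (proposal from the inverse Cholesky of a data-derived precision proxy;
  two extra density evaluations per iteration).
- **Initialisation.** Chains start from an L-BFGS optimum over the fixed
  effects with the innovations pinned at zero (optimising the full
  hierarchy would collapse onto the degenerate mode where tau inflates),
  plus a small chain-specific jitter.  This places warmup inside the
  typical set so the short adaptation windows see realistic scales.
- **Defaults.** 2 chains, 1000 warmup + 1000 kept draws, max tree depth 8,
  Q = 15 quadrature nodes.  Reduced settings used by the acceptance runs
  are listed below.

Posterior predictions: `predict_survival` computes per-draw
S_i(t) = exp(-CumHaz(entry_i, t)) with the subject's drawn random effects;
`predict_trajectory` returns the posterior mean trajectory and the WIV
band eta_mu(t) +/- z exp(eta_sigma(t)) (default z = 1.96).

`compute_loo` reports PSIS-LOO ELPD via ArviZ from per-subject
log-likelihood draws that are *conditional* on the subject's drawn random
effects (longitudinal terms plus event term); marginal LOO is out of
scope.  R-hat and ESS are rank-normalised split statistics from ArviZ; the
MCMC-SE column of `summarise_fit` is SD / sqrt(ESS).

## Simulator

`simulate_dataset` generates from the Cox-Exponential special case with LP
association: intercept + linear time in all four submodels, constant
baseline hazard lambda, covariates w1 ~ Bernoulli(0.5) and w2 ~ N(0, 1).
Substituting the linear predictors into the association collapses the log
hazard to log lambda + w'gamma + A_i + B t with

    A_i = sum_k [ a_mu_k (b0_mu_k + b_i_mu_k) + a_sig_k (b0_sig_k + b_i_sig_k) ]
    B   = sum_k [ a_mu_k b1_mu_k + a_sig_k b1_sig_k ]

so event times invert in closed form from a uniform draw; when B < 0 the
cumulative hazard is bounded and some draws never fail (returned as +inf,
then censored).  Censoring is uniform on (0, t_max); visits sit on a
regular grid (spacing 1) from 0 up to the observed time, with the t = 0
visit always present.  The inverse-CDF identity — Gauss–Kronrod cumulative
hazard at the drawn event time equals -log U — is asserted to 1e-8 in the
tests, tying the simulator to the hazard code through an independent
route.

Default generating values (the recovery targets used throughout):
beta_mu = (2.190, -0.040) and (1.040, 0.350); beta_sigma = (-1.360,
-0.020) and (0.160, 0.010); tau = (0.810, 0.520, 0.440, 0.160) in the
order (mu1, mu2, sigma1, sigma2); gamma = (0.930, -2.300); alpha =
(-2.240, 1.900, 0.550, 0.350) ordered (mu1, sigma1, mu2, sigma2).
Values the sources leave unspecified were fixed once from realism and kept:
lambda = 20 and t_max = 10, giving ~42% observed events and a median of
3-4 visits per subject (a registry-like follow-up); w1 probability 0.5;
random-effect correlations rho(mu1, mu2) = 0.5,
rho(mu1, sigma1) = rho(mu2, sigma2) = 0.4, others 0 (positive mean-mean
and mean-WIV correlations).

What the generator does *not* emulate: irregular or informative visit
schedules, missing visits, measurement error distinct from WIV, delayed
entry (left truncation is exercised directly in the hazard tests), and
competing risks.  Passing recovery tests therefore demonstrate correctness
of the estimation machinery under the model, not robustness to the ways
real registry data deviate from it.

## Evaluation harness and problem sizes

`run_simulation_study` repeats simulate → fit (WIV model and the
constant-variance comparator) → score.  The comparator restricts each
sigma submodel to a fixed intercept with no random effect and drops the
WIV association terms — the structure standard joint models assume.  Per
parameter it reports the truth, the mean and SD (eSD) of replicate
posterior means, and empirical 95% credible-interval coverage;
per replicate it records PSIS-LOO ELPD.  Replicate r uses seed
base_seed + r, so results are independent of execution order; failed fits
are logged and excluded, never silently dropped.

The acceptance runs use reduced problem sizes fixed once in
`jointwiv.presets` as the package's desk-scale configuration: a recovery
study of R = 4 replicates at N = 300 (2 chains x (250 + 250), max depth 7)
shared by the recovery, misspecification and ELPD-ordering checks; a
cheaper coverage study of R = 12 single-chain (150 + 150) fits for
credible-interval coverage; and a null-association fit at N = 200 with
2 chains x (300 + 300) at acceptance target 0.9 (the null posterior — a
bilinear ridge around each association coefficient at zero — is the
hardest geometry the package meets, and benefits from smaller steps).
The replicated studies evaluate the cumulative hazard with a 7-node
Gauss-Legendre rule: for the smooth penalized hazards these models
produce its relative error (~1e-6) is orders of magnitude below the
statistical noise, at half the cost of the default 15-node rule, which
single showcase fits keep.
Recovery is compared against the reference values with the tolerance
3 * eSD * sqrt(1000/N) / sqrt(R) + 0.02 * |reference|, i.e. the
replication noise of the reference study inflated by the 1/sqrt(N)
scaling of eSD at the smaller N.  Coverage at R = 12 has granularity
1/12.  The convergence gate (all reported R-hat <= 1.05, the scope a
results table reports: fixed effects, scales, correlations, smoothing
weight) is backed by one properly-lengthed fit at the default study
conditions (2 chains x (500 + 500)); the short replicate fits and the
null fit report their R-hat but are not individually gated — at those
chain lengths split-R-hat sits near 1.05-1.10 by Monte-Carlo noise alone.

Two caveats the reduced scale imposes.  First, log-hazard coefficients
carry the well-known small-sample magnitude inflation of proportional-
hazards estimation (about 120 events at N = 300), so the event-submodel
recovery means sit slightly further from zero than the reference values
obtained at N = 1000.  Second, the comparator's under-coverage signature
for the normal event covariate requires N = 1000-scale interval widths:
at N = 300 the comparator's bias (~0.3) is smaller than its interval
half-width (~0.7), so both models' intervals cover the truth and the
coverage contrast cannot be observed at this scale (the attenuation
contrast and the residual-spread absorption are observed).

## Numerical choices and edge cases

- Times outside the spline's knot span clamp to the boundary (constant
  extrapolation of log h0); prediction grids are restricted to the span.
- exp arguments are clipped at 350 before exponentiation; a non-finite log
  posterior or gradient is treated as a divergence (rejected), never
  propagated.
- A subject with entry = observed time contributes zero cumulative hazard;
  subjects with a single visit are allowed (no minimum-visit filter, which
  would introduce immortal-time selection).
- tau = 0 or tau_h outside (0, tau_h_scale) are outside the support:
  the natural-space density returns -inf and `pack_natural` raises.
- Degenerate chains (zero posterior SD) are flagged with NaN R-hat/MCMC-SE
  rather than reported as converged.

## Known limitations

- Gaussian outcomes only; no GAMLSS-style alternatives.
- The WIV is statistically indistinguishable from measurement error; for
  error-prone biomarkers the association is attenuated toward the null.
- Conditional (not marginal) per-subject likelihood in LOO.
- Single-panel Gauss–Kronrod quadrature: adequate for smooth penalized
  hazards (relative error ~1e-7 in the tests), but a very wiggly hazard
  across interior knots can reduce accuracy to ~1e-5.
- The affordable chain lengths trade some ESS on the correlation
  parameters; posterior means are stable but their interval endpoints
  carry extra Monte-Carlo noise at the reduced settings.
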