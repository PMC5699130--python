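# Methods

## Model

`cfjoint` fits a shared-parameter joint model for a longitudinal biomarker
and a censored event time. The longitudinal submodel is a Gaussian linear
mixed model for FEV₁ % predicted over age,

FEV1_ij = f(age_ij) + x1_ij'α1 + U0_i + U1_i·age_ij + ε_ij, ε ~ N(0, σ_ε²),

with f(age) a cubic truncated power basis spline: global monomials
1, a, a², a³ plus (a − κ_m)₊³ per interior knot. The event submodel is a
Weibull proportional-hazards model in time since study entry,
h_i(t) = k·t^(k−1)·exp(η_i), with η_i = x2_i'α2 + θ0·U0_i + θ1·U1_i and,
optionally, an independent frailty U3_i ~ N(0, σ3²) added to η (off by
default; it mainly absorbs event-risk heterogeneity the shared effects
cannot). The random effects (U0, U1) ~ N(0, Σ) are the only link between
the submodels, which are conditionally independent given them. Event-model
covariates are the baseline values (entry age, entry FEV₁, sex, birth
cohort, low SES); the event clock is time-on-study, with entry age as a
covariate, so predicted times convert to ages by adding the entry age.

Assumptions worth stating: trajectories are linear in the random effects
(level + slope deviations around a smooth population curve); the hazard is
Weibull given the effects (monotone in time when k ≠ 1); covariate effects
are proportional on the hazard; censoring is administrative and
non-informative given the random effects. Measurement stops at the first
exacerbation, which is exactly the informative-dropout mechanism the joint
model absorbs. Delayed entry (patients enter at varying ages conditional on
being alive and in care) is only partially addressed, via birth-cohort
covariates; the likelihood is not conditioned on entry time.

## Spline basis and knots

The basis dimension is 4 + K; K defaults to 6. Knots are placed at the K
equally spaced interior quantiles of the pooled visit ages (levels
m/(K+1)), a standard penalized-spline rule that adapts to uneven visit
density and is deterministic given the data. Ages enter on their natural
scale (years, not centered), so the intercept-related covariance σ01 is
interpretable at age 0 and curve coefficients match the usual reporting
convention. Setting K = 0 yields the global-cubic variant. Shrinkage of the
knot coefficients b_m ~ N(0, σ_b²), with an inverse-gamma hyperprior on
σ_b², is the spline penalization.

## Priors

WinBUGS-style vague defaults, all configurable through `PriorSpec`:
regression coefficients and θ0, θ1 ~ N(0, 10⁶); σ_ε² and σ3² ~
InvGamma(0.01, 0.01); Σ⁻¹ ~ Wishart(I₂, 2); k ~ Gamma(1, 0.001); spline
coefficients as above with σ_b² ~ InvGamma(0.01, 0.01).

## Sampler

The reference backend is a blocked Metropolis-within-Gibbs sampler in pure
numpy — chosen so the package has no external sampler dependency and runs
identically everywhere. Conjugate updates: the stacked fixed-effect vector
(multivariate normal, using the precomputed X'X), σ_ε² and σ_b²
(inverse-gamma), Σ (inverse-Wishart via a 2×2 Bartlett draw). Per-patient
(U0, U1) use one vectorized bivariate random-walk Metropolis step with a
proposal shaped by the current Σ and a per-patient adaptive scale; when no
event submodel is attached the exact bivariate-normal conditional is drawn
instead. The Weibull block (log k, α2, θ0, θ1) uses component-wise adaptive
random-walk Metropolis. Two internal reparameterizations improve mixing and
are inverted before draws are recorded: event covariates are mean-centered,
and follow-up times are scaled by their geometric mean to decorrelate k from
the intercept. Proposal scales adapt by Robbins–Monro only during burn-in
(target acceptance 0.40 scalar / 0.30 bivariate), so retained draws target
the exact posterior. Initialization is deterministic: least-squares fixed
effects, random effects at zero, method-of-moments variances, k = 1; a
non-finite start is retried with jitter up to 10 times. Defaults are 2
chains × 6,000 iterations with 1,000 burn-in; the test-suite experiments use
shorter chains (stated below). Split-chain R-hat and bulk ESS come from
arviz; HPD intervals are the shortest contiguous window containing
⌈0.95·n⌉ sorted draws, ties broken toward the smaller lower endpoint.

## DIC

Deviance is conditioned on the random effects (plug-in convention):
D = −2 log L(submodel | parameters, U). For each submodel DIC = D̄ + p_D
with p_D = D̄ − D(posterior means of all conditioned quantities, random
effects included); DIC_total = DIC₁ + DIC₂. The conditional convention is
deliberate: it makes p_D scale with the number of patients, which is the
behavior registry analyses report, and it is well-defined for every variant
here. Posterior means (not medians) define the plug-in point. The two-stage
variant fits the longitudinal submodel alone, then fits the event submodel
with each patient's posterior-mean (Û0, Û1) as fixed covariates; because
stage 2 ignores the uncertainty in Û, its association estimates attenuate
relative to the joint fit and its DIC falls between the joint and separate
fits.

## Synthetic registry generator

The generator emulates 2003–2011 US CF registry structure. Per patient:
entry age 6 + LogNormal(ln 4.8, 0.92) capped at 40 (median 10.8, IQR ≈
8.6–15); covariates drawn at reported prevalences (56% male, 35% low SES,
birth cohorts 13.5/15.3/27.9/43.3%, baseline Pa 20.7%, B. cepacia 2.5%)
and entry FEV₁ ~ N(92.3, 19.6²). Baseline CFRD (10%) and MRSA (15%) and
the monotone 0→1 onset rates of the time-varying flags (CFRD 0.02, MRSA
0.03, B. cepacia 0.003, Pa 0.05 per year) are not reported for the source
cohorts and are set to plausible CF-clinic values. Visits arrive as a
Poisson process at 4/year (quarterly clinic convention); the exacerbation
time is drawn by inverse transform from the Weibull hazard with the
patient's η; administrative censoring uses a horizon ~ Uniform(5, 9) years
(staggered entry into a ~9-year registry window) truncated at age 45;
longitudinal records stop at the first event. Default "true" parameters are
the package's registry-informed reference set (e.g. σ_ε² = 59.24, σ0² =
326.8, σ1² = 2.602, σ01 = −25.76, k = 2.564, θ0 = −0.0086, θ1 = −0.3532)
with knots fixed at (10, 15, 20, 25, 30, 35), under which the population
curve declines most steeply near age 17. Under these defaults a filtered
cohort shows ≈ 41% exacerbating and median follow-up ≈ 6.0 years,
matching registry summaries to within a few points.

What the generator does **not** emulate: encounter-level registry quirks
(hospitalization records, deduplication), visit-frequency feedback (sicker
patients visiting more often), correlation between birth cohort and entry
age, dependence of infections on lung function, or recurrent exacerbations.
Passing tests therefore demonstrate correctness of the machinery and
recoverability under the stated generative mechanism — not robustness to
real-registry misspecification.

## Cohort filters

Inclusion rules: visits outside the closed age window [6, 45] are dropped;
longitudinal records after the first recorded exacerbation are removed;
patients with fewer than 10 retained FEV₁ measurements are excluded;
baseline age/FEV₁ are (re)set from the first retained visit; every
exclusion is logged with a reason code. The minimum-visit count is applied
*after* event truncation by default — counting the measurements actually
analyzed — which also makes the filter idempotent; a flag restores the
count-before-truncation order. Recovery experiments fit the unfiltered
generator output, so the generative truth coincides exactly with the
fitted model (the filters reset baseline covariates from noisy first
visits, a registry realism that would otherwise blur the truth).

## Prediction

The population rate-of-decline curve is the analytic first derivative of
the basis applied per draw; the age of steepest decline is a 0.1-year grid
search per draw over [6, 45]. Hazard ratios per SD are exp(θ·σ) per draw
(point versions evaluate at posterior means). For a patient censored at c,
the conditional median event time solves S(t)/S(c) = ½ under that draw's
Weibull: t_med = (c^k + ln 2·e^(−η))^(1/k), the standard shared-parameter
construction; it is ≥ c by design and is reported both as time since entry
and as age.

## Numerical choices and experiment sizes

Invalid covariance proposals yield −∞ log posterior (rejection) rather than
exceptions. Duplicate (patient, age) rows and schema violations raise
distinct named errors at the I/O boundary. The simulation experiments in
the test suite are sized for a single CPU: recovery uses cohorts of 300
patients (20 replicates, chains of 2,500 with 1,000 burn-in) plus 12
cohorts of 100 for the bias-shrinkage contrast; the DIC-ordering experiment
uses 10 replicates of 300 patients at 1.5 visits/year with amplified
nonlinearity (spline coefficients ×2) and association (θ1 = −0.8), because
at a few hundred patients the event-submodel gain from the shared effects
at the reference effect sizes (~15 DIC units) is smaller than any
detectable spline-vs-cubic penalty; the amplified conditions preserve the
qualitative ordering semiparametric-joint < cubic-joint < separate at a
size where it is decidable.

## Known limitations

No delayed-entry (left-truncated) likelihood; no recurrent-event or
multivariate extension; no time-varying association W2(t); no dynamic
(landmark) prediction updating; single reference sampler backend (no HMC).
The event submodel treats covariates as fixed at baseline. DIC is the only
comparison criterion implemented (no WAIC/LOO).
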