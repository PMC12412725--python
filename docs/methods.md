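# Methods

## Model

`lsjoint` implements a location-scale joint model for a longitudinal marker
and K competing terminal events. The longitudinal submodel is a linear mixed
model whose residual standard deviation is itself subject-specific and
time-dependent:

    Y_ij = X_i(t_ij)' beta + Z_i(t_ij)' b_i + eps_ij,
    eps_ij ~ N(0, sigma_i(t_ij)^2),
    log sigma_i(t_ij) = O_i(t_ij)' mu + M_i(t_ij)' tau_i,

with Z and M sub-vectors of the design vectors X and O (both contain the
intercept), and (b_i, tau_i) jointly Gaussian with covariance Sigma. The
event submodels are cause-specific proportional hazards sharing the random
effects through three time-dependent features of the marker process — its
current error-free level, its current slope, and its current residual SD:

    lambda_ik(t) = lambda_0k(t) exp( W_ik' gamma_k
                   + alpha1_k ytilde_i(t) + alpha2_k ytilde_i'(t)
                   + alphaS_k sigma_i(t) ).

The residual-SD association is the scientific novelty: it asks whether the
*instability* of the marker (e.g. visit-to-visit blood-pressure
variability) carries risk information beyond its level and trend, while
avoiding the biases of two-stage summaries (conditioning on the future,
measurement error in an empirical SD).

Baseline hazards come in three variants: exponential, Weibull
(`kappa t^(kappa-1) e^zeta`), and cubic B-spline on the log scale with Q
interior knots (Q+4 coefficients). The B-spline order is cubic; interior
knots default to quantiles of the observed event times, boundary knots to 0
and the largest observed time, and beyond the boundary the log-baseline is
continued constantly at its boundary value so predictions past the last
event remain defined.

Time-to-event assumptions: censoring independent given covariates and the
marker-process features; the Markov-type dependence is on time-t features
only (no time lag); residuals are Gaussian.

## Likelihood and integration

The marginal likelihood integrates the product of the longitudinal Gaussian
density and the survival density over (b_i, tau_i). The integral is
approximated by quasi-Monte-Carlo: S Sobol points (Owen-scrambled, seeded;
the unscrambled variant skips the all-zeros point), mapped through the
inverse normal CDF and scaled by the Cholesky factor L of Sigma. The same
standard-normal point set is reused for every subject and every evaluation
(common random numbers), making the objective a smooth deterministic
function of theta during optimization. Per-subject averages are accumulated
with log-sum-exp.

Cumulative hazards use the 15-point Gauss-Kronrod rule. The scalar API
(`model_core.cumulative_hazard`, also used by the event-time sampler)
applies the rule after substituting v = u^kappa for Weibull baselines; the
substitution absorbs the t^(kappa-1) endpoint singularity so the rule is
exact when the relative hazard is constant and ~1e-10 accurate otherwise.
The batched likelihood evaluator keeps fixed nodes on [0, T_i] so that all
design matrices can be precomputed once; the two quadratures differ by
~1e-5 relative, far below statistical resolution at any realistic S.

Delayed entry (left truncation) is supported as an opt-in flag: each
subject's contribution is divided by the probability of being event-free at
the entry time, computed with the same QMC draws. The simulation scenarios
have no truncation, so the flag defaults to off.

QMC size matters: with 4 random effects and 5-13 visits per subject,
S = 64-128 visibly biases the variance components (checked against a
standard mixed-model fit and against S = 1024); S >= 256 is stable. The
package defaults are S1 = 500 and S2 = 5000; the scaled-down studies in the
test suite use S1 = 256, S2 = 384.

## Estimation

The log-likelihood is maximized by a damped Newton (Marquardt-Levenberg)
scheme. Derivatives are central finite differences with per-coordinate
steps max(h, h|theta_j|), h = 1e-4; the Hessian uses the four-point cross
stencil for off-diagonal entries. The cheaper first-order cross scheme was
tried and rejected: variance components near their boundary (the default
scenario truth has Var(tau0) = 1e-4) have third derivatives large enough to
corrupt it, destroying both the step direction and the standard errors.

At each iteration the diagonal of -H is inflated,

    A~_ii = A_ii + phi [ (1 - rho) |A_ii| + rho |tr A| ],

with phi escalating from 1e-2 by factors of 10 (rho moving to 0.5 after
repeated failures) until A~ admits a Cholesky factorization and the Newton
step improves the objective; a step-halving line search guards against
overshoot. Convergence requires three simultaneous criteria: parameter
stability (max squared step < 1e-4), function stability (|change| < 1e-4),
and relative distance to the maximum RDM = g' (-H)^{-1} g / m < 1e-3. When
-H is not positive definite (a ridge, or a boundary variance), RDM falls
back to the damped matrix actually used for the step; without the fallback
the loop can stall indefinitely at a stationary plateau.

Estimation proceeds in two steps: step 1 runs to convergence with S1 draws;
step 2 restarts with S2 draws and stops at the first iteration whose
Hessian is negative-definite with condition number below 1e12 (at least one
iteration); standard errors come from the inverse of that Hessian.
Covariance entries of Sigma are reported with Delta-method SEs through the
map L L'; the Weibull shape is estimated as log(kappa) and reported as
kappa with its Delta-method SE.

Initial values: a preliminary location-scale mixed model (the same
machinery with no event terms) started from a homoskedastic `MixedLM` fit,
plus per-cause parametric survival fits (lifelines Weibull/exponential,
mapped into the kappa/zeta parameterization) with all associations at zero.
The initializer warns when a random-effect variance comes out below 1e-3
(on the marker's mmHg-like scale), since an association through that effect
would be unidentifiable. Because the associations start at zero, the
marginal baseline absorbs the average association effect; `two_step_fit`
therefore pre-optimizes the per-cause survival blocks with the longitudinal
and covariance parameters held fixed (cheap, since the evaluator caches
unchanged likelihood components) before releasing all parameters. This
warm-up removes most of the ridge-following iterations of the full fit.

The evaluator caches likelihood components keyed by the byte content of the
parameter sub-vectors they depend on (longitudinal term, residual-SD field,
one survival term per cause), so finite-difference sweeps that perturb only
a survival coordinate skip the longitudinal work entirely.

## Empirical Bayes and dynamic prediction

Subject-specific random effects are summarized by the mode of
f(Y_i | b, tau) f(T_i, delta_i | b, tau) f(b, tau), found with the same
Marquardt-Levenberg routine (fallback: prior mean, with a warning). Marker
prediction bands are E(Y_i(t) | modes) +- 1.96 sigma_i(t) at the modal tau
— an SD-scale band, so a positive variance slope widens it over time.

The dynamic prediction pi_k(s, t) — the probability of a cause-k event in
(s, s+t] given event-free status at s and the marker history strictly
before s — is a ratio of QMC averages: each draw is weighted by the
conditional density of the observed history, the numerator integrates
g(u) lambda_k(u) over (s, s+t] with an outer Gauss-Kronrod rule and an
inner rule for each Lambda_c(0, u), and the denominator uses g(s), with
g(u) = exp(-sum_c Lambda_c(u)). Its 95% confidence interval is Monte-Carlo:
L parameter vectors drawn from N(theta_hat, V(theta_hat)) (default
L = 1000), pi recomputed for each, percentiles 2.5/97.5 reported. The
Cholesky/log-shape parameterization makes every draw a valid model, so no
rejection step is ever needed.

## Simulator

The generator emulates a blood-pressure-like cohort: marker
142 + b0 + (3 + b1) t with log residual SD 2.4 + tau0 + (0.05 + tau1) t;
visits at scheduled anchors jittered Uniform(+-1 month) and clipped at
zero; two Weibull cause-specific hazards, (kappa, zeta) = (1.1, -7) and
(1.3, -4), with associations (0.02, 0.01, 0.07) and (-0.01, -0.14, 0.15)
on (value, slope, sigma). Event times solve Lambda_k(t) = -log U by Brent
root-finding with a geometrically expanded bracket, capped at t_max = 100
years (beyond which the event never occurs). Censoring is the subject's
last scheduled visit; the observed time is the minimum of the two latent
event times and censoring; marker measures after it are dropped, and
subjects left with no visits are kept (they still contribute survival
information).

Scenario presets: A/B use independent b and tau blocks
(Var b = [[207.36, -17.28], [-17.28, 9.28]], Var tau =
[[1e-4, -6e-4], [-6e-4, 0.0157]]) with 7 (A) or 13 (B) visit anchors; C/D
use the full correlated 4x4 matrix with the same two schedules. E and F are
robustness scenarios with a single cause: E generates a quadratic marker
trend (default bend -0.3/year^2, no random curvature) to be fitted
linearly; F generates a constant within-subject SD (log-SD intercept 2.4,
Var(tau0) = 0.13, no slope) to be fitted with a linear trend. The E/F free
parameters are exposed as config overrides; their defaults above are the
package's own choice of a mild, realistic misspecification.

What the generator does not emulate: informative visit processes or
dropout, interval censoring, delayed entry, non-Gaussian measurement error,
covariate effects in the survival submodels. Passing tests therefore
demonstrate internal correctness and recovery under the stated generating
mechanisms, not robustness to those features of real cohorts.

## Evaluation harness

`evaluate.performance_measures` reports, per parameter, bias, empirical SE
(SD of estimates), mean asymptotic SE, and empirical coverage of Wald
intervals, excluding (but counting) non-converged replications;
`mc_error_coverage(level, R)` is the binomial Monte-Carlo error of a
coverage estimate. Coverage is assessed on the natural scale, with
Delta-method SEs for Sigma entries and kappa. The cause-specific
Nelson-Aalen estimator (Breslow-style tie handling) supports a
goodness-of-fit comparison of the mean model-based cumulative hazard at the
empirical-Bayes modes against its nonparametric counterpart, optionally
stratified.

## Reduced study sizes

The reference design for validating the estimation procedure is 300
replications of N=500 fits with S1=500/S2=5000 — many core-hours. The
package's own validation studies run a reduced design chosen once:
scenario A with N=200, 5 replications, S1=256/S2=384 for parameter
recovery; scenario B with N=150 for prediction calibration (8 subjects,
L=1000); scenario F with N=400, 5 replications for robustness — the
null-variance-trend property is asymptotic (the fixed log-SD slope
acquires a finite-sample bias of about -0.025 at N=150 that vanishes by
N=400), so that study keeps a large cohort and relaxes the stopping
tolerances instead. Study stopping tolerances are eps_param=1e-3,
eps_fn=5e-4 (recovery/calibration) and eps_param=1e-2, eps_fn=1e-3
(robustness). Thresholds are
adapted to the reduced replication count rather than loosened ad hoc: the
3-MC-SE bias rule becomes the t quantile with the same per-parameter tail
probability as the reference design's rule, the ASE/ESE band [0.7, 1.4] is
widened by the chi-square sampling factor of an ESE estimated from R-1
degrees of freedom, and coverage uses an exact binomial band.

## Known limitations

- Small cohorts can produce degenerate cause-specific likelihoods (a
  handful of events against five survival parameters); such fits converge
  to extreme baselines with very large SEs and are flagged only through
  their SEs.
- The optimizer follows the reference algorithm (fresh finite-difference
  Hessian every iteration); cost scales as ~2 m^2 likelihood evaluations
  per iteration, which dominates run time for m above ~25.
- Variance components sitting at their boundary (Var(tau0) truth 1e-4)
  show the expected mild undercoverage; the Cholesky parameterization keeps
  estimates valid but cannot remove the boundary effect.
- B-spline baselines are supported throughout but the simulation scenarios
  exercise Weibull baselines only.
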