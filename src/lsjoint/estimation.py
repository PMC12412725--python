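"""Maximum-likelihood estimation by the Marquardt-Levenberg algorithm.

The log-likelihood is maximized with a Levenberg-Marquardt-damped Newton
scheme: at each iteration the gradient and Hessian are computed by central
finite differences and the update solves the system with an *inflated*
Hessian whose diagonal is

    H~_ii = H_ii + phi * [ (1 - rho) |H_ii| + rho |tr(H)| ],

with (phi, rho) escalated until the damped matrix is definite and the step
improves the objective (a step-halving safeguard handles overshoot).
Convergence requires simultaneous parameter stability, function stability
and a small relative distance to the maximum, RDM = g' H^{-1} g / m.

Estimation of the joint model follows a two-step strategy: step 1 iterates
to convergence with a modest number of QMC draws (S1); step 2 restarts from
that solution with a larger number (S2) and stops as soon as the Hessian is
negative-definite and well-conditioned, from which standard errors are
taken.  Initial values come from a preliminary location-scale mixed model
fit (no event terms) plus cause-specific parametric survival fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .likelihood import LikelihoodEvaluator, QMCConfig
from .model_core import ModelSpec, ParameterVector, delta_method_se

__all__ = [
    "ControlSettings",
    "ConvergenceFlags",
    "FitResult",
    "fd_gradient",
    "fd_hessian",
    "fd_gradient_hessian",
    "marquardt_levenberg",
    "initialize",
    "two_step_fit",
]


@dataclass(frozen=True)
class ControlSettings:
    """Optimizer tolerances and QMC sizes for the two estimation steps."""

    eps_param: float = 1e-4    # threshold on max squared parameter change
    eps_fn: float = 1e-4       # threshold on objective change
    eps_d: float = 1e-3        # threshold on the relative distance to maximum
    max_iter: int = 60
    fd_step: float = 1e-4      # relative finite-difference step
    S1: int = 500
    S2: int = 5000

    def __post_init__(self):
        if min(self.eps_param, self.eps_fn, self.eps_d, self.fd_step) <= 0:
            raise ValueError("tolerances must be positive")
        if self.S2 < self.S1:
            raise ValueError("S2 must be at least S1")


@dataclass
class ConvergenceFlags:
    parameters: bool = False
    function: bool = False
    rdm: bool = False

    @property
    def all(self) -> bool:
        return self.parameters and self.function and self.rdm


@dataclass
class FitResult:
    """Outcome of a likelihood maximization."""

    theta_hat: np.ndarray
    loglik: float
    hessian: np.ndarray          # Hessian of the log-likelihood at theta_hat
    vcov: np.ndarray             # inverse of -H (asymptotic covariance)
    se: np.ndarray
    converged: ConvergenceFlags = field(default_factory=ConvergenceFlags)
    n_iter: int = 0
    rdm: float = np.inf
    spec: ModelSpec | None = None
    cov_se: np.ndarray | None = None  # Delta-method SEs of the Sigma entries
    param_names: list[str] | None = None
    message: str = ""

    @property
    def params(self) -> ParameterVector:
        if self.spec is None:
            raise ValueError("no ModelSpec attached to this result")
        return ParameterVector(self.spec, self.theta_hat)


# ---------------------------------------------------------------------------
# finite differences
# ---------------------------------------------------------------------------

def _steps(theta: np.ndarray, step: float) -> np.ndarray:
    return np.maximum(step, step * np.abs(theta))


def _safe_eval(fn, theta, what="objective"):
    v = fn(theta)
    if not np.isfinite(v):
        raise FloatingPointError(f"non-finite {what} value at theta={theta}")
    return v


def fd_gradient(fn, theta, step: float = 1e-4) -> np.ndarray:
    """Central-difference gradient with per-coordinate relative steps."""
    theta = np.asarray(theta, dtype=float)
    h = _steps(theta, step)
    g = np.empty_like(theta)
    for j in range(theta.size):
        e = np.zeros_like(theta)
        e[j] = h[j]
        g[j] = (fn(theta + e) - fn(theta - e)) / (2 * h[j])
    return g


def fd_hessian(fn, theta, step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian, symmetrized as (H + H') / 2."""
    _, H = fd_gradient_hessian(fn, theta, step)
    return H


def fd_gradient_hessian(fn, theta, step: float = 1e-4):
    """Gradient and Hessian sharing the axis evaluations.

    Central differences throughout: diagonal terms reuse the axis
    evaluations, off-diagonal terms use the four-point cross stencil.  The
    first-order cross scheme is avoided deliberately: variance components
    near their boundary produce third derivatives large enough to corrupt
    it, and an inaccurate Hessian both misguides the damped Newton step and
    invalidates the standard errors.

    If a perturbed evaluation is non-finite the step for that coordinate is
    shrunk once (factor 10); a second failure raises with the coordinate
    index.
    """
    theta = np.asarray(theta, dtype=float)
    m = theta.size
    h = _steps(theta, step)
    f0 = _safe_eval(fn, theta)

    fp = np.empty(m)
    fm = np.empty(m)
    for j in range(m):
        for attempt in range(2):
            e = np.zeros(m)
            e[j] = h[j]
            a, b = fn(theta + e), fn(theta - e)
            if np.isfinite(a) and np.isfinite(b):
                fp[j], fm[j] = a, b
                break
            h[j] /= 10.0
        else:
            raise FloatingPointError(
                f"non-finite perturbed objective along coordinate {j}")

    g = (fp - fm) / (2 * h)
    H = np.empty((m, m))
    H[np.diag_indices(m)] = (fp - 2 * f0 + fm) / h ** 2
    for i in range(m):
        ei = np.zeros(m); ei[i] = h[i]
        for j in range(i + 1, m):
            ej = np.zeros(m); ej[j] = h[j]
            v = (fn(theta + ei + ej) - fn(theta + ei - ej)
                 - fn(theta - ei + ej) + fn(theta - ei - ej)) / (4 * h[i] * h[j])
            H[i, j] = H[j, i] = v
    return g, H


# ---------------------------------------------------------------------------
# Marquardt-Levenberg maximization
# ---------------------------------------------------------------------------

def _inflate(A: np.ndarray, phi: float, rho: float) -> np.ndarray:
    """Damped curvature matrix for A = -H (positive-definite target)."""
    Ai = A.copy()
    d = np.abs(np.diag(A))
    Ai[np.diag_indices_from(A)] += phi * ((1 - rho) * d + rho * np.abs(np.trace(A)))
    return Ai


def _try_chol(A: np.ndarray):
    try:
        return np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        return None


def _rdm(g: np.ndarray, H: np.ndarray, fallback: np.ndarray | None = None) -> float:
    """Relative distance to the maximum, g' H^{-1} g / m (H = Hessian of ll).

    When -H is not positive-definite (a ridge or a variance component at its
    boundary) the criterion falls back to the damped curvature matrix that
    produced the accepted step, which is positive-definite by construction.
    """
    A = -H
    c = _try_chol(A)
    if c is None:
        if fallback is None:
            return np.inf
        c = _try_chol(fallback)
        if c is None:
            return np.inf
    w = np.linalg.solve(c, g)
    return float(w @ w) / g.size


def marquardt_levenberg(fn, theta0, control: ControlSettings | None = None,
                        stop_when_hessian_pd: bool = False,
                        logger=None) -> FitResult:
    """Maximize ``fn`` from ``theta0``.

    With ``stop_when_hessian_pd`` the loop additionally stops after the first
    iteration at which -H is positive-definite with condition number below
    1e12 (the refinement criterion of the second estimation step).
    """
    control = control or ControlSettings()
    theta = np.asarray(theta0, dtype=float).copy()
    f = _safe_eval(fn, theta, "objective at theta0")
    flags = ConvergenceFlags()
    rdm_val = np.inf
    g = np.zeros_like(theta)
    H = -np.eye(theta.size)
    message = "maximum iterations reached"
    n_iter = 0

    for n_iter in range(1, control.max_iter + 1):
        g, H = fd_gradient_hessian(fn, theta, control.fd_step)
        A = -H

        # escalate damping until the direction is defined and improves fn
        phi, rho = 1e-2, 0.0
        accepted = False
        A_tilde = None
        for attempt in range(25):
            A_tilde = _inflate(A, phi, rho)
            c = _try_chol(A_tilde)
            if c is None:
                phi *= 10.0
                if attempt >= 8:
                    rho = 0.5
                continue
            delta = np.linalg.solve(c.T, np.linalg.solve(c, g))
            psi = 1.0
            for _ in range(10):
                f_new = fn(theta + psi * delta)
                if np.isfinite(f_new) and f_new > f:
                    accepted = True
                    break
                psi *= 0.5
            if accepted:
                break
            phi *= 10.0
            if attempt >= 8:
                rho = 0.5
        rdm_val = _rdm(g, H, fallback=A_tilde)
        if not accepted:
            # no ascent step found: gradient is numerically at the maximum
            flags.parameters = flags.function = True
            flags.rdm = rdm_val < control.eps_d
            message = "no improving step found (objective stationary)"
            break

        step_vec = psi * delta
        theta = theta + step_vec
        df = f_new - f
        f = f_new
        if logger is not None:
            logger(n_iter, f, rdm_val, theta)

        flags.parameters = float(np.max(step_vec ** 2)) < control.eps_param
        flags.function = abs(df) < control.eps_fn
        flags.rdm = rdm_val < control.eps_d
        if flags.all:
            message = "converged (parameter, function and RDM criteria)"
            break
        if stop_when_hessian_pd:
            c = _try_chol(A)
            if c is not None:
                d = np.diag(c)
                cond2 = (d.max() / d.min()) ** 2 if d.min() > 0 else np.inf
                if cond2 < 1e12:
                    message = "stopped with invertible negative-definite Hessian"
                    break

    vcov, se = _vcov_from_hessian(H)
    return FitResult(theta_hat=theta, loglik=f, hessian=H, vcov=vcov, se=se,
                     converged=flags, n_iter=n_iter, rdm=rdm_val, message=message)


def _vcov_from_hessian(H: np.ndarray):
    A = -H
    try:
        vcov = np.linalg.inv(A)
        se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
    except np.linalg.LinAlgError:
        m = H.shape[0]
        vcov = np.full((m, m), np.nan)
        se = np.full(m, np.nan)
    return vcov, se


# ---------------------------------------------------------------------------
# initialization and the two-step joint fit
# ---------------------------------------------------------------------------

def _longitudinal_spec(spec: ModelSpec) -> ModelSpec:
    """The location-scale mixed model alone (event terms removed)."""
    return ModelSpec(design=spec.design, baselines=(), association=(),
                     re_structure=spec.re_structure)


def _lmm_starting_values(spec: ModelSpec, data):
    """Crude starting values from a standard homoskedastic mixed model."""
    import statsmodels.api as sm

    d = spec.design
    rows_X, rows_Z, y, groups = [], [], [], []
    for i, s in enumerate(data):
        if s.n_visits == 0:
            continue
        rows_X.append(d.X(s.visit_times, s.covariates))
        rows_Z.append(d.Z(s.visit_times))
        y.append(s.marker_values)
        groups.extend([i] * s.n_visits)
    X = np.vstack(rows_X)
    Z = np.vstack(rows_Z)
    y = np.concatenate(y)
    groups = np.asarray(groups)

    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    resid_var = float(np.var(y - X @ beta))
    Sigma_b = np.eye(d.n_b)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mm = sm.MixedLM(y, X, groups=groups, exog_re=Z).fit(reml=False, maxiter=200)
        beta = np.asarray(mm.fe_params)
        # statsmodels reports cov_re already on the response scale
        Sigma_b = np.asarray(mm.cov_re)
        resid_var = float(mm.scale)
    except Exception:   # singular fits fall back to least squares
        pass
    mu = np.zeros(d.n_mu)
    mu[0] = 0.5 * np.log(max(resid_var, 1e-8))
    Sigma = np.zeros((d.n_re, d.n_re))
    Sigma[:d.n_b, :d.n_b] = Sigma_b
    Sigma[d.n_b:, d.n_b:] = 0.01 * np.eye(d.n_tau)
    return beta, mu, Sigma


def _survival_starting_values(spec: ModelSpec, data):
    """Per-cause parametric baseline fits with all associations at zero."""
    from lifelines import ExponentialFitter, WeibullFitter

    T = np.array([max(s.obs_time, 1e-6) for s in data])
    baseline = []
    for k in range(1, spec.n_causes + 1):
        ev = np.array([s.event_code == k for s in data], dtype=float)
        bh = spec.baselines[k - 1]
        d_events = ev.sum()
        rate = max(d_events, 0.5) / T.sum()
        if bh.variant == "weibull":
            try:
                wf = WeibullFitter().fit(T, ev)
                # lifelines: H(t) = (t / lambda)^rho  ->  kappa = rho,
                # zeta0 = -rho log lambda
                kappa = float(wf.rho_)
                zeta0 = float(-wf.rho_ * np.log(wf.lambda_))
            except Exception:
                kappa, zeta0 = 1.0, np.log(rate)
            baseline.append(np.array([kappa, zeta0]))
        elif bh.variant == "exponential":
            try:
                ef = ExponentialFitter().fit(T, ev)
                baseline.append(np.array([-np.log(float(ef.lambda_))]))
            except Exception:
                baseline.append(np.array([np.log(rate)]))
        else:
            baseline.append(np.full(bh.n_params, np.log(rate)))
    return baseline


def initialize(spec: ModelSpec, data, control: ControlSettings | None = None,
               qmc: QMCConfig | None = None) -> ParameterVector:
    """Initial values from the preliminary location-scale mixed model.

    The mixed model with subject-specific residual variance is itself fitted
    by maximum likelihood (no event terms); survival parameters start at the
    cause-specific parametric fits with all association coefficients at zero.
    A warning names any random effect whose initialized variance is nearly
    null, since associations through that effect would then be unidentifiable.
    """
    control = control or ControlSettings()
    qmc = qmc or QMCConfig(S=control.S1)
    d = spec.design

    beta, mu, Sigma = _lmm_starting_values(spec, data)
    spec_long = _longitudinal_spec(spec)
    pv0 = ParameterVector.from_parts(spec_long, beta, mu, Sigma=Sigma)
    ev = LikelihoodEvaluator(spec_long, data, qmc)
    pre_control = replace(control, max_iter=min(control.max_iter, 20))
    fit = marquardt_levenberg(ev.total, pv0.flatten(), pre_control)
    pv_long = ParameterVector(spec_long, fit.theta_hat)

    var = np.diag(pv_long.Sigma)
    labels = [f"b{j}" for j in range(d.n_b)] + [f"tau{j}" for j in range(d.n_tau)]
    for lbl, v in zip(labels, var):
        if v < 1e-3:
            warnings.warn(f"random effect {lbl} has near-null variance ({v:.2e}); "
                          "associations through it may be unidentifiable",
                          stacklevel=2)

    baseline = _survival_starting_values(spec, data)
    return ParameterVector.from_parts(
        spec, pv_long.beta, pv_long.mu, chol=pv_long.chol, baseline=baseline)


def _survival_warmup(ev: LikelihoodEvaluator, theta0: np.ndarray,
                     control: ControlSettings) -> np.ndarray:
    """Pre-optimize the per-cause survival blocks with the rest held fixed.

    The association coefficients start at zero, so the baseline parameters
    from the marginal survival fits absorb the average association effect;
    letting (gamma, alpha, baseline) travel to their conditional values
    first is cheap — the evaluator caches the longitudinal and residual-SD
    components — and cuts most of the ridge-following iterations from the
    full fit.
    """
    spec = ev.spec
    d = spec.design
    start = d.n_beta + d.n_mu + spec.n_chol
    idx = np.arange(start, spec.n_params)
    if idx.size == 0:
        return theta0
    theta = theta0.copy()

    def fn(sub):
        th = theta.copy()
        th[idx] = sub
        return ev.total(th)

    warm_ctl = replace(control, max_iter=min(control.max_iter, 15), eps_d=1e-2)
    fit = marquardt_levenberg(fn, theta[idx], warm_ctl)
    theta[idx] = fit.theta_hat
    return theta


def two_step_fit(spec: ModelSpec, data, control: ControlSettings | None = None,
                 init: ParameterVector | None = None, qmc_seed: int = 0,
                 delayed_entry: bool = False, logger=None) -> FitResult:
    """Full maximum-likelihood fit of the joint model, two-step QMC strategy.

    After a survival-block warm-up from the initial values, step 1 iterates
    to convergence with S1 Sobol draws.  Step 2 restarts from that solution
    with S2 draws and performs at least one further iteration, stopping once
    the Hessian is invertible (negative-definite, condition number < 1e12);
    standard errors come from the step-2 Hessian.  If S1 == S2 the second
    step is skipped and the single-step result is finalized directly.
    """
    control = control or ControlSettings()
    if init is None:
        init = initialize(spec, data, control,
                          QMCConfig(S=min(control.S1, 256), scramble_seed=qmc_seed))
    theta0 = init.flatten() if isinstance(init, ParameterVector) else np.asarray(init)

    ev1 = LikelihoodEvaluator(spec, data, QMCConfig(S=control.S1, scramble_seed=qmc_seed),
                              delayed_entry=delayed_entry)
    theta0 = _survival_warmup(ev1, np.asarray(theta0, dtype=float), control)
    fit1 = marquardt_levenberg(ev1.total, theta0, control, logger=logger)

    if control.S2 == control.S1:
        final, ev_final = fit1, ev1
    else:
        ev2 = ev1.with_draws(QMCConfig(S=control.S2, scramble_seed=qmc_seed))
        fit2 = marquardt_levenberg(ev2.total, fit1.theta_hat, control,
                                   stop_when_hessian_pd=True, logger=logger)
        ok = np.all(np.isfinite(fit2.se))
        if not ok:
            warnings.warn("step-2 Hessian is not invertible; reporting step-1 "
                          "result", stacklevel=2)
            final, ev_final = fit1, ev1
        else:
            final, ev_final = fit2, ev2
            final.converged = ConvergenceFlags(
                parameters=fit1.converged.parameters or fit2.converged.parameters,
                function=fit1.converged.function or fit2.converged.function,
                rdm=fit1.converged.rdm or fit2.converged.rdm)

    final.spec = spec
    final.param_names = spec.param_names()
    d = spec.design
    sl = slice(d.n_beta + d.n_mu, d.n_beta + d.n_mu + spec.n_chol)
    if np.all(np.isfinite(final.vcov)):
        pv = final.params
        final.cov_se = delta_method_se(pv.chol, final.vcov[sl, sl],
                                       d.n_b, d.n_tau, spec.re_structure)
    return final
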