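"""Marginal likelihood of the location-scale joint model.

The subject-level likelihood integrates the product of the longitudinal
Gaussian density and the cause-specific survival density over the random
effects (b_i, tau_i):

    L_i = E_{(b,tau) ~ N(0, Sigma)} [ f(Y_i | b, tau) *
          exp(-sum_k Lambda_ik(T_i)) * prod_k lambda_ik(T_i)^{1(delta_i=k)} ]

The expectation has no closed form; it is approximated by quasi-Monte-Carlo:
Sobol points mapped through the inverse standard-normal CDF and scaled by the
Cholesky factor of Sigma.  The same base normal draws are reused for every
subject and every likelihood evaluation (common random numbers), so the
objective seen by the optimizer is a smooth deterministic function of theta.
Averages are accumulated with log-sum-exp throughout.

Two interfaces are provided: per-subject reference operations
(:func:`marginal_loglik_subject` etc.), and :class:`LikelihoodEvaluator`
which precomputes all design matrices and quadrature nodes once and
evaluates the total log-likelihood as a handful of dense array operations —
the workhorse behind estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, ndtri
from scipy.stats import qmc

from .model_core import (
    GK15_NODES,
    GK15_WEIGHTS,
    ModelSpec,
    ParameterVector,
    RandomEffects,
    SubjectRecord,
    cumulative_hazard,
    hazard,
    marker_mean,
    residual_sd,
)

__all__ = [
    "QMCConfig",
    "qmc_normal_draws",
    "loglik_longitudinal_given_re",
    "loglik_event_given_re",
    "marginal_loglik_subject",
    "delayed_entry_correction",
    "total_loglik",
    "LikelihoodEvaluator",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class QMCConfig:
    """Quasi-Monte-Carlo settings: S draws from a Sobol sequence.

    With ``scramble_seed`` set, Owen scrambling is applied (seeded, hence
    reproducible); otherwise the raw sequence is used and ``skip`` initial
    points are dropped so the all-zeros point never reaches the normal
    quantile function.
    """

    S: int = 500
    scramble_seed: int | None = 0
    skip: int = 1

    def __post_init__(self):
        if self.S < 2:
            raise ValueError("QMC sample size S must be at least 2")


def _standard_normal_sobol(cfg: QMCConfig, dim: int) -> np.ndarray:
    """(S, dim) standard-normal quasi-random matrix, deterministic given cfg."""
    if cfg.S < 2 ** dim:
        warnings.warn(f"S={cfg.S} is small for a {dim}-dimensional Sobol rule",
                      stacklevel=2)
    scramble = cfg.scramble_seed is not None
    sampler = qmc.Sobol(d=dim, scramble=scramble,
                        seed=cfg.scramble_seed if scramble else None)
    skip = cfg.skip if not scramble else 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        u = sampler.random(cfg.S + skip)[skip:]
    # guard the open interval (0,1) before the normal quantile
    eps = np.finfo(float).tiny
    return ndtri(np.clip(u, eps, 1.0 - eps))


def qmc_normal_draws(cfg: QMCConfig, dim: int, chol: np.ndarray | None = None) -> np.ndarray:
    """(S, dim) draws from N(0, L L') via the Sobol sequence.

    ``chol`` is the lower-triangular factor L; identity if omitted.
    """
    z = _standard_normal_sobol(cfg, dim)
    if chol is None:
        return z
    return z @ np.asarray(chol, dtype=float).T


# ---------------------------------------------------------------------------
# per-subject reference implementations
# ---------------------------------------------------------------------------

def loglik_longitudinal_given_re(spec: ModelSpec, subject: SubjectRecord,
                                 pv: ParameterVector, re: RandomEffects) -> float:
    """Sum over visits of log N(Y_ij; ytilde(t_ij), sigma(t_ij)^2)."""
    if subject.n_visits == 0:
        return 0.0
    d = spec.design
    t = subject.visit_times
    m = marker_mean(d, t, pv.beta, re.b, subject.covariates)
    log_sd = np.log(residual_sd(d, t, pv.mu, re.tau, subject.covariates))
    z = (subject.marker_values - m) * np.exp(-log_sd)
    return float(np.sum(-0.5 * _LOG2PI - log_sd - 0.5 * z * z))


def loglik_event_given_re(spec: ModelSpec, subject: SubjectRecord,
                          pv: ParameterVector, re: RandomEffects) -> float:
    """Survival log-density: -sum_k Lambda_k(T) + 1(delta=k) log lambda_k(T)."""
    if spec.n_causes == 0:     # longitudinal-only model: no event terms
        return 0.0
    T = subject.obs_time
    out = 0.0
    for k in range(1, spec.n_causes + 1):
        out -= cumulative_hazard(spec, subject, 0.0, T, pv, re, k)
    if subject.event_code > 0:
        out += float(np.log(hazard(spec, subject, T, pv, re, subject.event_code))[0])
    return out


def _re_from_row(spec: ModelSpec, row: np.ndarray) -> RandomEffects:
    n_b = spec.design.n_b
    return RandomEffects(row[:n_b], row[n_b:])


def marginal_loglik_subject(spec: ModelSpec, subject: SubjectRecord,
                            pv: ParameterVector, cfg: QMCConfig) -> float:
    """log of the QMC average of the conditional densities over S draws."""
    draws = qmc_normal_draws(cfg, spec.design.n_re, pv.L)
    ll = np.empty(cfg.S)
    for s in range(cfg.S):
        re = _re_from_row(spec, draws[s])
        ll[s] = (loglik_longitudinal_given_re(spec, subject, pv, re)
                 + loglik_event_given_re(spec, subject, pv, re))
    return float(logsumexp(ll) - np.log(cfg.S))


def delayed_entry_correction(spec: ModelSpec, subject: SubjectRecord,
                             pv: ParameterVector, cfg: QMCConfig) -> float:
    """log P(event-free at entry) <= 0, via the same QMC draws.

    Subtracting this from the subject's marginal log-likelihood conditions
    the contribution on survival up to the (delayed) entry time.
    """
    if subject.entry_time > subject.obs_time:
        raise ValueError(f"subject {subject.id}: entry after observed time")
    if subject.entry_time == 0.0:
        return 0.0
    draws = qmc_normal_draws(cfg, spec.design.n_re, pv.L)
    ll = np.empty(cfg.S)
    for s in range(cfg.S):
        re = _re_from_row(spec, draws[s])
        ll[s] = -sum(cumulative_hazard(spec, subject, 0.0, subject.entry_time, pv, re, k)
                     for k in range(1, spec.n_causes + 1))
    return float(logsumexp(ll) - np.log(cfg.S))


def total_loglik(spec: ModelSpec, data, theta, cfg: QMCConfig,
                 delayed_entry: bool = False) -> float:
    """Sum of per-subject marginal log-likelihood contributions."""
    if len(data) == 0:
        raise ValueError("empty dataset")
    pv = theta if isinstance(theta, ParameterVector) else ParameterVector(spec, theta)
    total = 0.0
    for subject in data:
        li = marginal_loglik_subject(spec, subject, pv, cfg)
        if delayed_entry:
            li -= delayed_entry_correction(spec, subject, pv, cfg)
        if not np.isfinite(li):
            raise FloatingPointError(
                f"non-finite likelihood contribution for subject {subject.id}")
        total += li
    return total


# ---------------------------------------------------------------------------
# vectorized evaluator
# ---------------------------------------------------------------------------

class LikelihoodEvaluator:
    """Batched total log-likelihood with cached designs and QMC draws.

    All visit-level and quadrature-node-level design matrices, Gauss-Kronrod
    weights, and the standard-normal Sobol matrix are computed once at
    construction; evaluating the log-likelihood at a new theta then reduces
    to dense matrix products and exponentials.  Agreement with the
    per-subject reference path is exercised in the test suite.
    """

    def __init__(self, spec: ModelSpec, data, cfg: QMCConfig,
                 delayed_entry: bool = False):
        if len(data) == 0:
            raise ValueError("empty dataset")
        self.spec = spec
        self.data = list(data)
        self.cfg = cfg
        self.delayed_entry = delayed_entry
        self._z = _standard_normal_sobol(cfg, spec.design.n_re)  # (S, d)
        self._cache = {}
        self._cache_bytes = 0
        self._prepare()

    # -- construction of the static arrays --
    def _prepare(self):
        spec, data = self.spec, self.data
        d = spec.design
        N = len(data)
        self.N = N

        # longitudinal stack, grouped by subject
        ys, counts = [], []
        for s in data:
            ys.append(s.marker_values)
            counts.append(s.n_visits)
        self.y = np.concatenate(ys)
        self.counts = np.asarray(counts)
        starts = np.concatenate([[0], np.cumsum(self.counts)[:-1]])
        self._nonempty = np.flatnonzero(self.counts > 0)
        self._starts_nonempty = starts[self._nonempty]

        _needs_cov = {"X": True, "O": True, "dX": True, "Z": False,
                      "dZ": False, "M": False}

        def stack_design(times_per_subject, which):
            """vstack of the design built per subject (covariates constant)."""
            needs_cov = _needs_cov[which]
            blocks = []
            for t, s in zip(times_per_subject, data):
                fn = getattr(d, which)
                blocks.append(fn(t, s.covariates) if needs_cov else fn(t))
            return np.vstack(blocks)

        t_visits = [s.visit_times for s in data]
        # visit-level designs (row per observation)
        self.Xo = stack_design(t_visits, "X")
        self.Zo = stack_design(t_visits, "Z")
        self.Oo = stack_design(t_visits, "O")
        self.Mo = stack_design(t_visits, "M")

        # Gauss-Kronrod nodes for Lambda_k(0, T_i): 15 per subject
        T = np.array([s.obs_time for s in data])
        self.T = T
        self.delta = np.array([s.event_code for s in data])
        half = 0.5 * T
        tn = half[:, None] + half[:, None] * GK15_NODES[None, :]   # (N, 15)
        self.wn = half[:, None] * GK15_WEIGHTS[None, :]
        tn_flat = tn.ravel()
        t_nodes = list(tn)
        self.Xn = stack_design(t_nodes, "X")
        self.dXn = stack_design(t_nodes, "dX")
        self.Zn = stack_design(t_nodes, "Z")
        self.dZn = stack_design(t_nodes, "dZ")
        self.On = stack_design(t_nodes, "O")
        self.Mn = stack_design(t_nodes, "M")
        self.tn_flat = tn_flat

        # designs at the observed time T_i (hazard of the realized cause)
        t_T = [np.array([ti]) for ti in T]
        self.XT = stack_design(t_T, "X")
        self.dXT = stack_design(t_T, "dX")
        self.ZT = stack_design(t_T, "Z")
        self.dZT = stack_design(t_T, "dZ")
        self.OT = stack_design(t_T, "O")
        self.MT = stack_design(t_T, "M")

        # per-cause survival covariate matrices and B-spline bases
        self.Wg = []
        self.Bn = []
        self.BT = []
        for k in range(1, spec.n_causes + 1):
            if spec.n_gamma(k):
                self.Wg.append(np.array([d.W(k, s.covariates) for s in data]))
            else:
                self.Wg.append(np.zeros((N, 0)))
            bh = spec.baselines[k - 1]
            if bh.variant == "bspline":
                self.Bn.append(bh.basis_matrix(tn_flat))
                self.BT.append(bh.basis_matrix(T))
            else:
                self.Bn.append(None)
                self.BT.append(None)
        with np.errstate(divide="ignore"):
            self.log_tn = np.log(tn_flat)
            self.log_T = np.log(T)

        # delayed-entry nodes on [0, T0_i]
        entry = np.array([s.entry_time for s in data])
        self.entry = entry
        self._any_entry = self.delayed_entry and bool(np.any(entry > 0))
        if self._any_entry:
            halfe = 0.5 * entry
            te2 = halfe[:, None] + halfe[:, None] * GK15_NODES[None, :]
            te = te2.ravel()
            self.we = halfe[:, None] * GK15_WEIGHTS[None, :]
            t_e = list(te2)
            self.Xe = stack_design(t_e, "X")
            self.dXe = stack_design(t_e, "dX")
            self.Ze = stack_design(t_e, "Z")
            self.dZe = stack_design(t_e, "dZ")
            self.Oe = stack_design(t_e, "O")
            self.Me = stack_design(t_e, "M")
            self.te_flat = te
            self.Be = []
            with np.errstate(divide="ignore"):
                self.log_te = np.log(te)
            for k in range(1, spec.n_causes + 1):
                bh = spec.baselines[k - 1]
                self.Be.append(bh.basis_matrix(te) if bh.variant == "bspline" else None)

    # -- evaluation --
    #
    # Likelihood components are cached by the byte content of the parameter
    # sub-vectors they depend on.  During a finite-difference sweep most
    # evaluations perturb one or two coordinates, so e.g. perturbing a
    # survival parameter of cause 2 reuses the longitudinal term, the
    # residual-SD field and the cause-1 term unchanged.
    _CACHE_LIMIT_BYTES = 3e8

    def _cached(self, name, key, builder):
        k = (name, key)
        hit = self._cache.get(k)
        if hit is not None:
            return hit
        val = builder()
        if self._cache_bytes > self._CACHE_LIMIT_BYTES:
            self._cache.clear()
            self._cache_bytes = 0
        self._cache[k] = val
        self._cache_bytes += getattr(val, "nbytes", 0) or sum(
            getattr(v, "nbytes", 0) for v in val)
        return val

    def _draws(self, pv: ParameterVector):
        kc = pv.chol.tobytes()

        def build():
            re = self._z @ pv.L.T                   # (S, d)
            n_b = self.spec.design.n_b
            return re[:, :n_b].T.copy(), re[:, n_b:].T.copy()

        return self._cached("draws", kc, build)

    def _log_baseline(self, pv, k, which):
        bh = self.spec.baselines[k - 1]
        p = pv.baseline(k)
        if which == "nodes":
            logt, B = self.log_tn, self.Bn[k - 1]
        elif which == "T":
            logt, B = self.log_T, self.BT[k - 1]
        else:
            logt, B = self.log_te, self.Be[k - 1]
        if bh.variant == "exponential":
            return np.full_like(logt, p[0])
        if bh.variant == "weibull":
            kappa, zeta0 = p
            return np.log(kappa) + (kappa - 1.0) * logt + zeta0
        return B @ p

    def _surv_key(self, pv, k):
        i0 = self._surv_slices(pv)[k - 1]
        return pv.theta[i0].tobytes()

    def _surv_slices(self, pv):
        return [slice(pv._sl_gamma[j].start, pv._sl_base[j].stop)
                for j in range(self.spec.n_causes)]

    def _sd_field(self, pv, tauT, nodes):
        km = pv.mu.tobytes() + pv.chol.tobytes()
        On, Mn = (self.On, self.Mn) if nodes == "event" else (self.Oe, self.Me)

        def build():
            return np.exp((On @ pv.mu)[:, None] + Mn @ tauT)

        return self._cached("sd_" + nodes, km, build)

    def _event_cause_term(self, pv, bT, tauT, k, nodes="event"):
        """(N, S): -Lambda_k over the node set (+ delta log-hazard at T)."""
        spec = self.spec
        if nodes == "event":
            Xn, dXn, Zn, dZn = self.Xn, self.dXn, self.Zn, self.dZn
            wn, which = self.wn, "nodes"
        else:
            Xn, dXn, Zn, dZn = self.Xe, self.dXe, self.Ze, self.dZe
            wn, which = self.we, "entry"
        S = bT.shape[1]
        N = self.N
        sd_n = self._sd_field(pv, tauT, nodes)
        a = pv.alpha(k)
        a1, a2 = a.get("value", 0.0), a.get("slope", 0.0)
        out = np.zeros((N, S))
        with np.errstate(over="ignore"):
            # fixed (column) part of the log-hazard
            col = self._log_baseline(pv, k, which) + a1 * (Xn @ pv.beta) \
                + a2 * (dXn @ pv.beta)
            g = pv.gamma(k)
            if g.size:
                col = col + np.repeat(self.Wg[k - 1] @ g, 15)
            # random part: single matmul for the value+slope terms
            lam = (a1 * Zn + a2 * dZn) @ bT
            if "sigma" in a:
                lam += a["sigma"] * sd_n
            lam += col[:, None]
            np.exp(lam, out=lam)
            out -= np.einsum("nq,nqs->ns", wn, lam.reshape(N, 15, S))
        if nodes == "entry":
            return out
        # hazard at T_i for the realized cause
        mask = self.delta == k
        if np.any(mask):
            lin = self._log_baseline(pv, k, "T")[mask][:, None] \
                + np.zeros((int(mask.sum()), S))
            g = pv.gamma(k)
            if g.size:
                lin += (self.Wg[k - 1][mask] @ g)[:, None]
            if a1:
                lin += a1 * ((self.XT[mask] @ pv.beta)[:, None]
                             + self.ZT[mask] @ bT)
            if a2:
                lin += a2 * ((self.dXT[mask] @ pv.beta)[:, None]
                             + self.dZT[mask] @ bT)
            if "sigma" in a:
                lin += a["sigma"] * np.exp((self.OT[mask] @ pv.mu)[:, None]
                                           + self.MT[mask] @ tauT)
            out[mask] += lin
        return out

    def _event_loglik_draws(self, pv, bT, tauT, nodes="event"):
        """(N, S) log of the survival density (or log survival to entry)."""
        base_key = pv.beta.tobytes() + pv.mu.tobytes() + pv.chol.tobytes()
        out = np.zeros((self.N, bT.shape[1]))
        for k in range(1, self.spec.n_causes + 1):
            key = base_key + self._surv_key(pv, k)
            out = out + self._cached(
                ("ev" if nodes == "event" else "ent") + str(k), key,
                lambda: self._event_cause_term(pv, bT, tauT, k, nodes))
        return out

    def _long_loglik_draws(self, pv, bT, tauT):
        S = bT.shape[1]
        if self.y.size == 0:
            return np.zeros((self.N, S))
        mean_o = (self.Xo @ pv.beta)[:, None] + self.Zo @ bT
        log_sd = (self.Oo @ pv.mu)[:, None] + self.Mo @ tauT
        z = (self.y[:, None] - mean_o) * np.exp(-log_sd)
        ll_obs = -0.5 * _LOG2PI - log_sd - 0.5 * z * z
        out = np.zeros((self.N, S))
        out[self._nonempty] = np.add.reduceat(ll_obs, self._starts_nonempty, axis=0)
        return out

    def subject_logliks(self, theta) -> np.ndarray:
        """Per-subject marginal log-likelihood contributions at theta."""
        pv = theta if isinstance(theta, ParameterVector) else ParameterVector(self.spec, theta)
        bT, tauT = self._draws(pv)
        key_long = pv.beta.tobytes() + pv.mu.tobytes() + pv.chol.tobytes()
        ll = self._cached("long", key_long,
                          lambda: self._long_loglik_draws(pv, bT, tauT)) \
            + self._event_loglik_draws(pv, bT, tauT)
        out = logsumexp(ll, axis=1) - np.log(self.cfg.S)
        if self._any_entry:
            ll0 = self._event_loglik_draws(pv, bT, tauT, nodes="entry")
            corr = logsumexp(ll0, axis=1) - np.log(self.cfg.S)
            out = out - np.where(self.entry > 0, corr, 0.0)
        return out

    def total(self, theta) -> float:
        ll = self.subject_logliks(theta)
        if not np.all(np.isfinite(ll)):
            bad = [self.data[i].id for i in np.flatnonzero(~np.isfinite(ll))]
            warnings.warn(f"non-finite likelihood contribution for subjects {bad}; "
                          "returning -inf-protected value", stacklevel=2)
            ll = np.where(np.isfinite(ll), ll, -1e10)
        return float(np.sum(ll))

    def __call__(self, theta) -> float:
        return self.total(theta)

    def with_draws(self, cfg: QMCConfig) -> "LikelihoodEvaluator":
        """A new evaluator over the same data with a different QMC rule."""
        return LikelihoodEvaluator(self.spec, self.data, cfg,
                                   delayed_entry=self.delayed_entry)
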