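"""Synthetic cohorts from the location-scale joint model.

The generator emulates a blood-pressure-like marker followed over five
years with competing terminal events.  The default truth is

    Y(t)   = 142 + b0 + (3 + b1) t + eps(t),
    log sigma(t) = 2.4 + tau0 + (0.05 + tau1) t,

with Weibull baseline hazards and associations on the current value, the
current slope and the current residual SD of the marker:

    lambda_1(t) = kappa1 t^(kappa1-1) e^{zeta1} exp(0.02 y~ + 0.01 y~' + 0.07 sigma)
    lambda_2(t) = kappa2 t^(kappa2-1) e^{zeta2} exp(-0.01 y~ - 0.14 y~' + 0.15 sigma)

with (kappa1, zeta1) = (1.1, -7) and (kappa2, zeta2) = (1.3, -4).  Visit
times are scheduled anchors jittered uniformly by +-1 month; each latent
event time solves Lambda_k(t) = -log U by Brent root-finding; censoring
occurs at the subject's last scheduled visit, the observed time is the
minimum of the two latent event times and censoring, and marker measures
after the observed time are discarded.

Six named scenarios are provided: A/B (independent b and tau; sparse/dense
visit schedules), C/D (correlated random effects), and the robustness
scenarios E (quadratic marker trend in the truth, to be fitted linearly)
and F (constant within-subject variance in the truth, to be fitted with a
time trend); E and F have a single event cause.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model_core import (
    BaselineHazard,
    DesignSpec,
    ModelSpec,
    ParameterVector,
    RandomEffects,
    SubjectRecord,
    cumulative_hazard,
    polynomial_basis,
)

__all__ = [
    "CauseTruth",
    "ScenarioConfig",
    "scenario_config",
    "truth_spec",
    "truth_params",
    "fitting_spec",
    "generate_visits",
    "generate_subject_data",
    "generate_event_time",
    "assemble_dataset",
    "SCENARIO_ANCHORS",
]

ONE_MONTH = 1.0 / 12.0

# visit anchors: sparse = 7 measurement times; dense = 13 (every 3 months
# the first year, then twice per year until 5 years)
SCENARIO_ANCHORS = {
    "sparse": np.array([0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0]),
    "dense": np.array([0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5,
                       3.0, 3.5, 4.0, 4.5, 5.0]),
}

_SIGMA_INDEP = np.block([
    [np.array([[207.36, -17.28], [-17.28, 9.28]]), np.zeros((2, 2))],
    [np.zeros((2, 2)), np.array([[0.0001, -0.0006], [-0.0006, 0.0157]])],
])

_SIGMA_CORR = np.array([
    [210.25, -15.95, 2.9, -0.145],
    [-15.95, 9.05, -0.304, 0.067],
    [2.9, -0.304, 0.1309, -0.0206],
    [-0.145, 0.067, -0.0206, 0.0141],
])

_CAUSE1 = dict(kappa=1.1, zeta0=-7.0, alpha_value=0.02, alpha_slope=0.01,
               alpha_sigma=0.07)
_CAUSE2 = dict(kappa=1.3, zeta0=-4.0, alpha_value=-0.01, alpha_slope=-0.14,
               alpha_sigma=0.15)


@dataclass(frozen=True)
class CauseTruth:
    """Weibull baseline and association coefficients for one cause."""

    kappa: float
    zeta0: float
    alpha_value: float = 0.0
    alpha_slope: float = 0.0
    alpha_sigma: float = 0.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete generating truth for one simulation scenario."""

    name: str
    N: int
    beta: np.ndarray
    mu: np.ndarray
    Sigma: np.ndarray
    causes: tuple[CauseTruth, ...]
    anchors: np.ndarray
    jitter: float = ONE_MONTH
    random_mean_idx: tuple[int, ...] = (0, 1)
    random_var_idx: tuple[int, ...] = (0, 1)
    t_max: float = 100.0

    def __post_init__(self):
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "Sigma", np.asarray(self.Sigma, dtype=float))
        object.__setattr__(self, "anchors", np.asarray(self.anchors, dtype=float))
        eig = np.linalg.eigvalsh(self.Sigma)
        if eig.min() < -1e-10:
            raise ValueError("Sigma is not positive semi-definite")
        if np.any(np.diff(self.anchors) <= 0):
            raise ValueError("visit anchors must be increasing")


def scenario_config(name: str, N: int = 500, **overrides) -> ScenarioConfig:
    """Named scenario presets A-F.

    E and F expose free parameters through ``overrides``; their defaults are
    a mild quadratic bend (E) and a constant log-SD with the intercept
    variance of the correlated scenarios (F).
    """
    name = name.upper()
    base = dict(N=N, beta=np.array([142.0, 3.0]), mu=np.array([2.4, 0.05]),
                causes=(CauseTruth(**_CAUSE1), CauseTruth(**_CAUSE2)))
    if name == "A":
        kw = dict(base, Sigma=_SIGMA_INDEP, anchors=SCENARIO_ANCHORS["sparse"])
    elif name == "B":
        kw = dict(base, Sigma=_SIGMA_INDEP, anchors=SCENARIO_ANCHORS["dense"])
    elif name == "C":
        kw = dict(base, Sigma=_SIGMA_CORR, anchors=SCENARIO_ANCHORS["sparse"])
    elif name == "D":
        kw = dict(base, Sigma=_SIGMA_CORR, anchors=SCENARIO_ANCHORS["dense"])
    elif name == "E":
        # quadratic truth for the marker mean, single cause
        kw = dict(base, beta=np.array([142.0, 3.0, -0.3]), Sigma=_SIGMA_INDEP,
                  anchors=SCENARIO_ANCHORS["sparse"],
                  causes=(CauseTruth(**_CAUSE1),))
    elif name == "F":
        # constant within-subject variance, single cause
        Sigma = np.zeros((3, 3))
        Sigma[:2, :2] = _SIGMA_INDEP[:2, :2]
        Sigma[2, 2] = 0.13
        kw = dict(base, mu=np.array([2.4]), Sigma=Sigma,
                  anchors=SCENARIO_ANCHORS["sparse"],
                  causes=(CauseTruth(**_CAUSE1),),
                  random_var_idx=(0,))
    else:
        raise ValueError(f"unknown scenario {name!r} (expected A-F)")
    kw.update(overrides)
    return ScenarioConfig(name=name, **kw)


# ---------------------------------------------------------------------------
# generating-model specification
# ---------------------------------------------------------------------------

def truth_spec(cfg: ScenarioConfig) -> ModelSpec:
    """ModelSpec matching the generating model exactly."""
    design = DesignSpec(
        mean_basis=polynomial_basis(len(cfg.beta) - 1),
        var_basis=polynomial_basis(len(cfg.mu) - 1),
        random_mean_idx=cfg.random_mean_idx,
        random_var_idx=cfg.random_var_idx,
    )
    baselines = tuple(BaselineHazard("weibull") for _ in cfg.causes)
    return ModelSpec(design=design, baselines=baselines,
                     association=tuple(("value", "slope", "sigma") for _ in cfg.causes),
                     re_structure="full")


def truth_params(cfg: ScenarioConfig) -> ParameterVector:
    """The generating parameters as a ParameterVector over truth_spec."""
    spec = truth_spec(cfg)
    alpha = [dict(value=c.alpha_value, slope=c.alpha_slope, sigma=c.alpha_sigma)
             for c in cfg.causes]
    baseline = [np.array([c.kappa, c.zeta0]) for c in cfg.causes]
    return ParameterVector.from_parts(spec, cfg.beta, cfg.mu, Sigma=cfg.Sigma,
                                      alpha=alpha, baseline=baseline)


def fitting_spec(cfg: ScenarioConfig) -> ModelSpec:
    """The model estimated in the study: linear trends for mean and log-SD,
    Weibull baselines, value+slope+sigma associations.

    The random effects are left unstructured for the correlated scenarios
    (C, D) and block-independent otherwise.  Note this is deliberately
    misspecified for scenarios E (quadratic truth) and F (constant-variance
    truth).
    """
    design = DesignSpec(mean_basis=polynomial_basis(1), var_basis=polynomial_basis(1),
                        random_mean_idx=(0, 1), random_var_idx=(0, 1))
    baselines = tuple(BaselineHazard("weibull") for _ in cfg.causes)
    structure = "full" if cfg.name in ("C", "D") else "independent"
    return ModelSpec(design=design, baselines=baselines,
                     association=tuple(("value", "slope", "sigma") for _ in cfg.causes),
                     re_structure=structure)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_visits(cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """One subject's visit times: anchors jittered by +-jitter, clipped at 0."""
    t = cfg.anchors + rng.uniform(-cfg.jitter, cfg.jitter, size=cfg.anchors.size)
    t = np.sort(np.clip(t, 0.0, None))
    # duplicates can only arise from clipping at zero; nudge them apart
    for j in range(1, t.size):
        if t[j] <= t[j - 1]:
            t[j] = t[j - 1] + 1e-6
    return t


def _draw_random_effects(cfg: ScenarioConfig, rng: np.random.Generator) -> RandomEffects:
    w, V = np.linalg.eigh(cfg.Sigma)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    u = L @ rng.standard_normal(cfg.Sigma.shape[0])
    n_b = len(cfg.random_mean_idx)
    return RandomEffects(u[:n_b], u[n_b:])


def generate_subject_data(cfg: ScenarioConfig, rng: np.random.Generator,
                          subject_id=0, _spec: ModelSpec | None = None
                          ) -> tuple[SubjectRecord, RandomEffects]:
    """Marker history before censoring/event truncation, plus the latent
    random effects used to generate it."""
    spec = _spec if _spec is not None else truth_spec(cfg)
    d = spec.design
    re = _draw_random_effects(cfg, rng)
    t = generate_visits(cfg, rng)
    mean = d.X(t) @ cfg.beta + d.Z(t) @ re.b
    sd = np.exp(d.O(t) @ cfg.mu + d.M(t) @ re.tau)
    y = mean + sd * rng.standard_normal(t.size)
    rec = SubjectRecord(id=subject_id, entry_time=0.0, obs_time=float(t[-1]),
                        event_code=0, visit_times=t, marker_values=y)
    return rec, re


def generate_event_time(cfg: ScenarioConfig, re: RandomEffects, cause: int,
                        u: float, _spec: ModelSpec | None = None,
                        _pv: ParameterVector | None = None) -> float:
    """Latent event time solving Lambda_k(t) = -log(u) by Brent root-finding.

    Returns +inf when no event occurs before ``cfg.t_max``.
    """
    spec = _spec if _spec is not None else truth_spec(cfg)
    pv = _pv if _pv is not None else truth_params(cfg)
    target = -np.log(u)

    def surplus(t):
        return cumulative_hazard(spec, None, 0.0, t, pv, re, cause) - target

    hi = 1.0
    while surplus(hi) < 0.0:
        hi *= 2.0
        if hi > cfg.t_max:
            return np.inf
    return float(brentq(surplus, 0.0, hi, xtol=1e-10, rtol=1e-12))


def assemble_dataset(cfg: ScenarioConfig, seed: int = 0,
                     return_effects: bool = False):
    """Simulate a full dataset: visits, marker, competing events, censoring.

    Censoring time is the subject's last scheduled (jittered) visit; the
    observed time is the minimum of the latent cause-specific event times
    and censoring, and visits after it are dropped.  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    spec, pv = truth_spec(cfg), truth_params(cfg)
    data, effects = [], []
    for i in range(cfg.N):
        rec, re = generate_subject_data(cfg, rng, subject_id=i, _spec=spec)
        C = rec.obs_time
        uu = rng.uniform(size=len(cfg.causes))
        t_star = [generate_event_time(cfg, re, k + 1, uu[k], _spec=spec, _pv=pv)
                  for k in range(len(cfg.causes))]
        T = min(min(t_star), C)
        delta = 0 if T == C else int(np.argmin(t_star)) + 1
        keep = rec.visit_times <= T + 1e-12
        data.append(SubjectRecord(id=i, entry_time=0.0, obs_time=float(T),
                                  event_code=delta,
                                  visit_times=rec.visit_times[keep],
                                  marker_values=rec.marker_values[keep]))
        effects.append(re)
    if return_effects:
        return data, effects
    return data
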