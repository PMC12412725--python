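"""Replication-study performance measures and goodness-of-fit tools.

Follows the ADEMP convention for reporting simulation studies: for each
parameter the bias of the mean estimate, the empirical standard error (SD
of the estimates across replications), the mean asymptotic standard error,
and the empirical coverage of nominal Wald confidence intervals, together
with the Monte-Carlo error of a coverage estimate.  A cause-specific
Nelson-Aalen estimator supports comparing the fitted model's mean predicted
cumulative hazard (at the empirical-Bayes random-effect modes) with its
nonparametric counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model_core import ModelSpec, ParameterVector, cumulative_hazard

__all__ = [
    "PerformanceTable",
    "performance_measures",
    "mc_error_coverage",
    "StepFunction",
    "nelson_aalen",
    "gof_cumhaz_comparison",
    "natural_parameter_table",
    "scenario_truth_table",
    "run_replications",
]


@dataclass
class PerformanceTable:
    """Per-parameter simulation performance measures over R replications."""

    table: pd.DataFrame       # truth, mean, bias, ese, ase, cr columns
    n_replications: int
    n_converged: int

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def performance_measures(estimates, ses, truth, level: float = 0.95,
                         names=None, converged=None) -> PerformanceTable:
    """Bias, ESE, ASE and coverage of Wald intervals across replications.

    ``estimates`` and ``ses`` are (R, m) arrays; replications flagged
    non-converged are excluded from every measure but counted.
    """
    estimates = np.asarray(estimates, dtype=float)
    ses = np.asarray(ses, dtype=float)
    truth = np.asarray(truth, dtype=float)
    R_all = estimates.shape[0]
    if converged is not None:
        mask = np.asarray(converged, dtype=bool)
        estimates, ses = estimates[mask], ses[mask]
    R = estimates.shape[0]
    if R < 2:
        raise ValueError("at least two converged replications required")
    z = norm.ppf(0.5 + level / 2)
    mean = estimates.mean(axis=0)
    bias = mean - truth
    ese = estimates.std(axis=0, ddof=1)
    ase = ses.mean(axis=0)
    covered = (np.abs(estimates - truth) <= z * ses)
    cr = 100.0 * covered.mean(axis=0)
    if names is None:
        names = [f"param{j}" for j in range(len(truth))]
    table = pd.DataFrame({"truth": truth, "mean": mean, "bias": bias,
                          "ese": ese, "ase": ase, "cr": cr}, index=names)
    return PerformanceTable(table=table, n_replications=R_all, n_converged=R)


def mc_error_coverage(level: float, R: int) -> float:
    """Monte-Carlo standard error (in %) of an estimated coverage rate."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if R < 1:
        raise ValueError("R must be positive")
    return 100.0 * float(np.sqrt(level * (1 - level) / R))


# ---------------------------------------------------------------------------
# Nelson-Aalen and model-based goodness of fit
# ---------------------------------------------------------------------------

@dataclass
class StepFunction:
    """Right-continuous step function with jumps at ``times``."""

    times: np.ndarray
    values: np.ndarray

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            out = np.zeros_like(t)
            return out if out.ndim else 0.0
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 0.0)
        return out if out.ndim else float(out)


def nelson_aalen(times, status, cause: int = 1) -> StepFunction:
    """Cause-specific Nelson-Aalen cumulative hazard.

    Jump d_kj / n_j at each time with d_kj events of the given cause, n_j
    the number still at risk; ties aggregate their event count at the tied
    time.  Subjects with other causes or censoring leave the risk set
    without contributing a jump.
    """
    times = np.asarray(times, dtype=float)
    status = np.asarray(status)
    if np.any(times < 0):
        raise ValueError("negative event times")
    order = np.argsort(times, kind="stable")
    t_sorted, s_sorted = times[order], status[order]
    uniq, start = np.unique(t_sorted, return_index=True)
    n = len(times)
    jumps, jump_times = [], []
    at_risk = n
    for j, t in enumerate(uniq):
        end = start[j + 1] if j + 1 < len(uniq) else n
        d_k = int(np.sum(s_sorted[start[j]:end] == cause))
        if d_k and at_risk > 0:
            jump_times.append(t)
            jumps.append(d_k / at_risk)
        at_risk -= end - start[j]
    return StepFunction(np.asarray(jump_times),
                        np.cumsum(jumps) if jumps else np.asarray([]))


def gof_cumhaz_comparison(spec: ModelSpec, data, pv: ParameterVector,
                          modes, cause: int = 1, strata=None):
    """Mean model-based cumulative hazard versus its Nelson-Aalen estimator.

    At each cause-specific event time the model curve averages
    Lambda_k(0, t) over the subjects still at risk at t, with the random
    effects fixed at their empirical-Bayes modes.  ``modes`` is the list of
    RandomEffects aligned with ``data``.  With ``strata`` (a list of labels
    per subject) one pair of curves is returned per stratum as a dict.
    """
    if strata is not None:
        out = {}
        for lev in sorted(set(strata)):
            idx = [i for i, s in enumerate(strata) if s == lev]
            out[lev] = gof_cumhaz_comparison(
                spec, [data[i] for i in idx], pv, [modes[i] for i in idx], cause)
        return out

    T = np.array([s.obs_time for s in data])
    status = np.array([s.event_code for s in data])
    na = nelson_aalen(T, status, cause)
    grid = na.times if na.times.size else np.array([np.median(T)])
    model_curve = np.zeros_like(grid)
    for j, t in enumerate(grid):
        at_risk = T >= t
        vals = [cumulative_hazard(spec, data[i], 0.0, t, pv, modes[i], cause)
                for i in np.flatnonzero(at_risk)]
        model_curve[j] = np.mean(vals) if vals else np.nan
    return pd.DataFrame({"time": grid, "nelson_aalen": na(grid),
                         "model": model_curve})


# ---------------------------------------------------------------------------
# natural-scale reporting and replicated simulation studies
# ---------------------------------------------------------------------------

def _sigma_entry_names(spec: ModelSpec):
    """Unique (row, col) pairs of Sigma reported for this structure."""
    d = spec.design
    n_b, n_tau = d.n_b, d.n_tau
    pairs = []
    if spec.re_structure == "independent":
        pairs += [(i, j) for i in range(n_b) for j in range(i + 1)]
        pairs += [(n_b + i, n_b + j) for i in range(n_tau) for j in range(i + 1)]
    else:
        n = n_b + n_tau
        pairs += [(i, j) for i in range(n) for j in range(i + 1)]
    return pairs


def natural_parameter_table(fit) -> pd.DataFrame:
    """Estimates and SEs on the natural (reported) scale.

    Fixed effects and association coefficients pass through; the entries of
    Sigma and the Weibull shape get Delta-method standard errors (the model
    is fitted on the Cholesky / log-shape scale).
    """
    spec = fit.spec
    pv = fit.params
    d = spec.design
    rows = []
    for j in range(d.n_beta):
        rows.append(("beta%d" % j, pv.beta[j], fit.se[j]))
    off = d.n_beta
    for j in range(d.n_mu):
        rows.append(("mu%d" % j, pv.mu[j], fit.se[off + j]))
    Sigma = pv.Sigma
    cov_se = fit.cov_se if fit.cov_se is not None else np.full(Sigma.shape, np.nan)
    for (r, s) in _sigma_entry_names(spec):
        rows.append((f"sigma_{r}{s}", Sigma[r, s], cov_se[r, s]))
    i = d.n_beta + d.n_mu + spec.n_chol
    for k in range(1, spec.n_causes + 1):
        for c in (d.surv_covariates[k - 1] if d.surv_covariates else ()):
            rows.append((f"gamma{k}_{c}", fit.theta_hat[i], fit.se[i])); i += 1
        for term in spec.association[k - 1]:
            rows.append((f"alpha_{term}{k}", fit.theta_hat[i], fit.se[i])); i += 1
        bh = spec.baselines[k - 1]
        if bh.variant == "weibull":
            kappa = np.exp(fit.theta_hat[i])
            rows.append((f"kappa{k}", kappa, kappa * fit.se[i])); i += 1
            rows.append((f"zeta{k}", fit.theta_hat[i], fit.se[i])); i += 1
        else:
            for j in range(bh.n_params):
                rows.append((f"baseline{k}_{j}", fit.theta_hat[i], fit.se[i])); i += 1
    return pd.DataFrame(rows, columns=["name", "estimate", "se"])


def scenario_truth_table(cfg, spec: ModelSpec) -> pd.DataFrame:
    """Generating truth aligned with natural_parameter_table's names.

    ``cfg`` is a simulation ScenarioConfig whose generating model is nested
    in (or equal to) the fitted ``spec``; truth entries absent from the
    generating model (e.g. a variance time-slope under a constant-variance
    truth) are zero.
    """
    d = spec.design
    rows = []
    beta = np.zeros(d.n_beta)
    beta[:min(len(cfg.beta), d.n_beta)] = cfg.beta[:d.n_beta]
    for j in range(d.n_beta):
        rows.append((f"beta{j}", beta[j]))
    mu = np.zeros(d.n_mu)
    mu[:min(len(cfg.mu), d.n_mu)] = cfg.mu[:d.n_mu]
    for j in range(d.n_mu):
        rows.append((f"mu{j}", mu[j]))
    n = d.n_re
    Sigma = np.zeros((n, n))
    n_b_true = len(cfg.random_mean_idx)
    n_tau_true = len(cfg.random_var_idx)
    St = cfg.Sigma
    Sigma[:n_b_true, :n_b_true] = St[:n_b_true, :n_b_true]
    Sigma[d.n_b:d.n_b + n_tau_true, d.n_b:d.n_b + n_tau_true] = \
        St[n_b_true:, n_b_true:]
    Sigma[:n_b_true, d.n_b:d.n_b + n_tau_true] = St[:n_b_true, n_b_true:]
    Sigma[d.n_b:d.n_b + n_tau_true, :n_b_true] = St[n_b_true:, :n_b_true]
    for (r, s) in _sigma_entry_names(spec):
        rows.append((f"sigma_{r}{s}", Sigma[r, s]))
    for k, c in enumerate(cfg.causes, start=1):
        for term, val in (("value", c.alpha_value), ("slope", c.alpha_slope),
                          ("sigma", c.alpha_sigma)):
            if term in spec.association[k - 1]:
                rows.append((f"alpha_{term}{k}", val))
        rows.append((f"kappa{k}", c.kappa))
        rows.append((f"zeta{k}", c.zeta0))
    return pd.DataFrame(rows, columns=["name", "value"])


def run_replications(cfg, spec: ModelSpec, R: int, control, base_seed: int = 0,
                     progress=None) -> dict:
    """Replicated simulate-fit cycles for one scenario.

    Returns arrays of natural-scale estimates and SEs (R x m), convergence
    flags, the parameter names, and the aligned truth.  Replication r uses
    dataset seed ``base_seed + r`` and QMC seed ``base_seed + r``.
    """
    from .estimation import two_step_fit
    from .simulate import assemble_dataset

    est_rows, se_rows, conv = [], [], []
    names = truth = None
    for r in range(R):
        data = assemble_dataset(cfg, seed=base_seed + r)
        fit = two_step_fit(spec, data, control, qmc_seed=base_seed + r)
        tab = natural_parameter_table(fit)
        if names is None:
            names = tab["name"].tolist()
            truth = scenario_truth_table(cfg, spec).set_index("name") \
                .loc[names, "value"].to_numpy()
        est_rows.append(tab["estimate"].to_numpy(dtype=float))
        se_rows.append(tab["se"].to_numpy(dtype=float))
        conv.append(bool(fit.converged.all or fit.converged.rdm
                         or np.all(np.isfinite(fit.se))))
        if progress is not None:
            progress(r, fit)
    return {"estimates": np.array(est_rows), "ses": np.array(se_rows),
            "converged": np.array(conv), "names": names, "truth": truth}
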