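"""Marginal likelihood: QMC draws, conditional densities, integration
against quadrature oracles, delayed entry, and the batched evaluator."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import multivariate_normal, norm

from lsjoint.likelihood import (
    LikelihoodEvaluator,
    QMCConfig,
    delayed_entry_correction,
    loglik_event_given_re,
    loglik_longitudinal_given_re,
    marginal_loglik_subject,
    qmc_normal_draws,
    total_loglik,
)
from lsjoint.model_core import (
    ParameterVector,
    RandomEffects,
    SubjectRecord,
    build_chol,
    chol_params_from_cov,
)

from conftest import make_spec

SIGMA_A = np.block([
    [np.array([[207.36, -17.28], [-17.28, 9.28]]), np.zeros((2, 2))],
    [np.zeros((2, 2)), np.array([[0.0001, -0.0006], [-0.0006, 0.0157]])],
])


def _subject(visits, values, T=5.0, delta=0, entry=0.0, sid=0):
    return SubjectRecord(sid, entry, T, delta, np.asarray(visits, float),
                         np.asarray(values, float))


class TestQMCDraws:
    def test_deterministic(self):
        cfg = QMCConfig(S=256, scramble_seed=7)
        a = qmc_normal_draws(cfg, 4)
        b = qmc_normal_draws(cfg, 4)
        np.testing.assert_array_equal(a, b)

    def test_mean_near_zero(self):
        cfg = QMCConfig(S=4096, scramble_seed=1)
        z = qmc_normal_draws(cfg, 4)
        sd = z.std(axis=0)
        assert np.all(np.abs(z.mean(axis=0)) < 3 * sd / np.sqrt(z.shape[0]))

    def test_covariance_matches_target(self):
        cfg = QMCConfig(S=5000, scramble_seed=0)
        L = build_chol(chol_params_from_cov(SIGMA_A, 2, 2, "full"), 2, 2, "full")
        draws = qmc_normal_draws(cfg, 4, L)
        emp = np.cov(draws.T)
        rel = np.linalg.norm(emp - SIGMA_A) / np.linalg.norm(SIGMA_A)
        assert rel <= 0.05

    def test_unscrambled_skips_origin(self):
        cfg = QMCConfig(S=8, scramble_seed=None, skip=1)
        z = qmc_normal_draws(cfg, 2)
        assert np.all(np.isfinite(z))


class TestConditionalLogliks:
    def test_single_observation_at_mean_unit_sd(self):
        spec = make_spec()
        # mean 10 at t=0 via intercept, sigma=1 via mu=0
        pv = ParameterVector.from_parts(spec, [10.0, 0.0], [0.0, 0.0],
                                        Sigma=np.eye(4),
                                        baseline=[np.array([1.0, -3.0])])
        sub = _subject([0.0], [10.0])
        re = RandomEffects([0.0, 0.0], [0.0, 0.0])
        got = loglik_longitudinal_given_re(spec, sub, pv, re)
        assert got == pytest.approx(np.log(1 / np.sqrt(2 * np.pi)), abs=1e-10)

    def test_matches_scalar_gaussian_oracle(self):
        spec = make_spec()
        rng = np.random.default_rng(2)
        pv = ParameterVector.from_parts(spec, [140.0, 2.0], [2.0, 0.1],
                                        Sigma=np.eye(4),
                                        baseline=[np.array([1.0, -3.0])])
        re = RandomEffects(rng.normal(size=2), 0.05 * rng.normal(size=2))
        t = np.array([0.0, 1.0, 2.5, 4.0])
        y = 140 + 2 * t + rng.normal(size=4) * 5
        sub = _subject(t, y)
        d = spec.design
        mean = (140 + re.b[0]) + (2 + re.b[1]) * t
        sd = np.exp((2.0 + re.tau[0]) + (0.1 + re.tau[1]) * t)
        expected = norm.logpdf(y, mean, sd).sum()
        assert loglik_longitudinal_given_re(spec, sub, pv, re) \
            == pytest.approx(expected, rel=1e-12)

    def test_decreasing_in_residual_magnitude(self):
        spec = make_spec()
        pv = ParameterVector.from_parts(spec, [0.0, 0.0], [0.0, 0.0],
                                        Sigma=np.eye(4),
                                        baseline=[np.array([1.0, -3.0])])
        re = RandomEffects([0.0, 0.0], [0.0, 0.0])
        lls = [loglik_longitudinal_given_re(spec, _subject([1.0], [dev]), pv, re)
               for dev in (0.0, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(lls) < 0)

    def test_zero_visits_contribute_nothing(self):
        spec = make_spec()
        pv = ParameterVector.from_parts(spec, [1.0, 0.0], [0.0, 0.0],
                                        Sigma=np.eye(4),
                                        baseline=[np.array([1.0, -3.0])])
        sub = _subject([], [])
        re = RandomEffects([0.0, 0.0], [0.0, 0.0])
        assert loglik_longitudinal_given_re(spec, sub, pv, re) == 0.0


class TestEventLoglik:
    def test_censored_with_negligible_hazard(self):
        spec = make_spec(baselines=("exponential",), association=(("value",),))
        pv = ParameterVector.from_parts(spec, [0.0, 0.0], [0.0, 0.0],
                                        Sigma=np.eye(4),
                                        alpha=[dict(value=0.0)],
                                        baseline=[np.array([-800.0])])
        re = RandomEffects([0.0, 0.0], [0.0, 0.0])
        assert loglik_event_given_re(spec, _subject([0.0], [0.0]), pv, re) \
            == pytest.approx(0.0, abs=1e-300)

    def test_constant_hazard_exponential_likelihood(self):
        c, T = 0.23, 3.1
        spec = make_spec(baselines=("exponential",), association=(("value",),))
        pv = ParameterVector.from_parts(spec, [0.0, 0.0], [0.0, 0.0],
                                        Sigma=np.eye(4),
                                        alpha=[dict(value=0.0)],
                                        baseline=[np.array([np.log(c)])])
        re = RandomEffects([0.0, 0.0], [0.0, 0.0])
        got = loglik_event_given_re(spec, _subject([0.0], [0.0], T=T, delta=1),
                                    pv, re)
        assert got == pytest.approx(-c * T + np.log(c), rel=1e-10)

    def test_two_cause_weibull_closed_form(self):
        spec = make_spec(baselines=("weibull", "weibull"))
        k1, z1, k2, z2 = 1.1, -2.0, 1.4, -1.5
        pv = ParameterVector.from_parts(
            spec, [0.0, 0.0], [0.0, 0.0], Sigma=np.eye(4),
            alpha=[dict(value=0, slope=0, sigma=0)] * 2,
            baseline=[np.array([k1, z1]), np.array([k2, z2])])
        re = RandomEffects([0.0, 0.0], [0.0, 0.0])
        T = 2.2
        expected = (-T ** k1 * np.exp(z1) - T ** k2 * np.exp(z2)
                    + np.log(k2 * T ** (k2 - 1) * np.exp(z2)))
        got = loglik_event_given_re(spec, _subject([0.0], [0.0], T=T, delta=2),
                                    pv, re)
        assert got == pytest.approx(expected, rel=1e-8)


def _one_dim_re_spec_pv(sigma_b=3.0, sigma_meas=2.0, beta0=10.0, c=0.1,
                        alpha_value=0.0):
    """Random-intercept-only model (tau variance null) for quadrature oracles."""
    spec = make_spec(baselines=("exponential",), association=(("value",),))
    Sigma = np.zeros((4, 4))
    Sigma[0, 0] = sigma_b ** 2
    pv = ParameterVector.from_parts(spec, [beta0, 0.0],
                                    [np.log(sigma_meas), 0.0], Sigma=Sigma,
                                    alpha=[dict(value=alpha_value)],
                                    baseline=[np.array([np.log(c)])])
    return spec, pv


class TestMarginalLoglik:
    def test_matches_closed_form_lmm(self):
        """With null event weight and homogeneous variance the QMC marginal
        approaches the Gaussian linear-mixed-model marginal density."""
        spec = make_spec(baselines=("exponential",), association=(("value",),))
        sigma_meas = 2.0
        Sigma = np.zeros((4, 4))
        Sigma[:2, :2] = np.array([[9.0, 1.0], [1.0, 1.0]])
        pv = ParameterVector.from_parts(spec, [140.0, 3.0],
                                        [np.log(sigma_meas), 0.0], Sigma=Sigma,
                                        alpha=[dict(value=0.0)],
                                        baseline=[np.array([-800.0])])
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        rng = np.random.default_rng(0)
        y = 140 + 3 * t + rng.normal(size=5)
        sub = _subject(t, y)
        X = np.column_stack([np.ones(5), t])
        V = X @ Sigma[:2, :2] @ X.T + sigma_meas ** 2 * np.eye(5)
        expected = multivariate_normal.logpdf(y, 140 + 3 * t, V)
        got = marginal_loglik_subject(spec, sub, pv,
                                      QMCConfig(S=5000, scramble_seed=0))
        assert got == pytest.approx(expected, rel=1e-3)

    def test_qmc_stabilizes_with_more_draws(self):
        spec, pv = _one_dim_re_spec_pv(alpha_value=0.05)
        sub = _subject([0.0, 1.0, 3.0], [11.0, 9.0, 12.0], T=4.0, delta=1)
        vals = [marginal_loglik_subject(spec, sub, pv,
                                        QMCConfig(S=S, scramble_seed=0))
                for S in (250, 500, 2000, 4000)]
        diffs = np.abs(np.diff(vals))
        assert diffs[-1] < diffs[0]

    def test_one_dimensional_matches_adaptive_quadrature(self):
        spec, pv = _one_dim_re_spec_pv(alpha_value=0.08)
        sub = _subject([0.0, 1.0, 3.0], [11.0, 9.0, 12.0], T=4.0, delta=1)
        sigma_b = 3.0

        def integrand(b0):
            re = RandomEffects([b0, 0.0], [0.0, 0.0])
            ll = (loglik_longitudinal_given_re(spec, sub, pv, re)
                  + loglik_event_given_re(spec, sub, pv, re))
            return np.exp(ll) * norm.pdf(b0, 0, sigma_b)

        ref, _ = quad(integrand, -8 * sigma_b, 8 * sigma_b,
                      epsabs=1e-14, epsrel=1e-12, limit=300)
        got = marginal_loglik_subject(spec, sub, pv,
                                      QMCConfig(S=8192, scramble_seed=0))
        assert got == pytest.approx(np.log(ref), abs=1e-4)


class TestDelayedEntry:
    def test_zero_entry_no_correction(self):
        spec, pv = _one_dim_re_spec_pv()
        sub = _subject([0.0], [10.0], T=4.0)
        assert delayed_entry_correction(spec, sub, pv, QMCConfig(S=64)) == 0.0

    def test_constant_hazard_closed_form(self):
        # hazard free of random effects: log P(T > T0) = -c T0
        c = 0.3
        spec, pv = _one_dim_re_spec_pv(c=c, alpha_value=0.0)
        sub = _subject([2.0], [10.0], T=4.0, entry=1.7)
        got = delayed_entry_correction(spec, sub, pv,
                                       QMCConfig(S=512, scramble_seed=0))
        assert got == pytest.approx(-c * 1.7, rel=1e-10)

    def test_one_dimensional_matches_quadrature(self):
        spec, pv = _one_dim_re_spec_pv(alpha_value=0.1)
        T0 = 2.0
        sub = _subject([2.5], [10.0], T=4.0, entry=T0)
        sigma_b = 3.0

        def integrand(b0):
            re = RandomEffects([b0, 0.0], [0.0, 0.0])
            from lsjoint.model_core import cumulative_hazard
            lam = cumulative_hazard(spec, sub, 0.0, T0, pv, re, 1)
            return np.exp(-lam) * norm.pdf(b0, 0, sigma_b)

        ref, _ = quad(integrand, -8 * sigma_b, 8 * sigma_b,
                      epsabs=1e-14, epsrel=1e-12, limit=300)
        got = delayed_entry_correction(spec, sub, pv,
                                       QMCConfig(S=8192, scramble_seed=0))
        assert got == pytest.approx(np.log(ref), abs=1e-4)

    def test_entry_after_observed_time_rejected(self):
        spec, pv = _one_dim_re_spec_pv()
        with pytest.raises(ValueError):
            sub = SubjectRecord(0, 5.0, 4.0, 0, [2.0], [10.0])
            delayed_entry_correction(spec, sub, pv, QMCConfig(S=64))


class TestTotalLoglik:
    def test_single_subject_equals_marginal(self, spec_a, data_a, truth_pv_a):
        cfg = QMCConfig(S=128, scramble_seed=0)
        sub = data_a[0]
        assert total_loglik(spec_a, [sub], truth_pv_a, cfg) \
            == pytest.approx(marginal_loglik_subject(spec_a, sub, truth_pv_a, cfg))

    def test_duplication_doubles(self, spec_a, data_a, truth_pv_a):
        cfg = QMCConfig(S=64, scramble_seed=0)
        subset = data_a[:4]
        one = total_loglik(spec_a, subset, truth_pv_a, cfg)
        two = total_loglik(spec_a, subset + subset, truth_pv_a, cfg)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_permutation_invariant(self, spec_a, data_a, truth_pv_a):
        cfg = QMCConfig(S=64, scramble_seed=0)
        subset = data_a[:6]
        a = total_loglik(spec_a, subset, truth_pv_a, cfg)
        b = total_loglik(spec_a, subset[::-1], truth_pv_a, cfg)
        assert a == pytest.approx(b, rel=1e-12)

    def test_empty_dataset_rejected(self, spec_a, truth_pv_a):
        with pytest.raises(ValueError, match="empty"):
            total_loglik(spec_a, [], truth_pv_a, QMCConfig(S=64))

    def test_factorizes_when_associations_null(self, data_a):
        """With alpha = 0 the joint likelihood splits into the location-scale
        mixed model part plus a parametric survival part."""
        spec = make_spec(baselines=("weibull", "weibull"))
        Sigma = SIGMA_A.copy()
        pv = ParameterVector.from_parts(
            spec, [142.0, 3.0], [2.4, 0.05], Sigma=Sigma,
            alpha=[dict(value=0, slope=0, sigma=0)] * 2,
            baseline=[np.array([1.1, -7.0]), np.array([1.3, -4.0])])
        cfg = QMCConfig(S=256, scramble_seed=0)
        subset = data_a[:25]
        joint = total_loglik(spec, subset, pv, cfg)

        spec_long = make_spec(baselines=())
        pv_long = ParameterVector.from_parts(spec_long, [142.0, 3.0],
                                             [2.4, 0.05], Sigma=Sigma)
        long_part = total_loglik(spec_long, subset, pv_long, cfg)

        surv_part = 0.0
        for s in subset:
            T = s.obs_time
            for k, (kap, zet) in enumerate([(1.1, -7.0), (1.3, -4.0)], start=1):
                surv_part -= T ** kap * np.exp(zet)
                if s.event_code == k:
                    surv_part += np.log(kap * T ** (kap - 1)) + zet
        assert joint == pytest.approx(long_part + surv_part, rel=1e-9)


class TestBatchedEvaluator:
    def test_matches_reference_path(self, spec_a, data_a, truth_pv_a):
        cfg = QMCConfig(S=64, scramble_seed=3)
        subset = data_a[:10]
        ref = total_loglik(spec_a, subset, truth_pv_a, cfg)
        ev = LikelihoodEvaluator(spec_a, subset, cfg)
        # reference path integrates the Weibull baseline on a transformed
        # axis, the batched path on fixed nodes: they agree to quadrature error
        assert ev.total(truth_pv_a.flatten()) == pytest.approx(ref, rel=1e-5)

    def test_matches_reference_with_delayed_entry(self, spec_a, truth_pv_a):
        rng = np.random.default_rng(1)
        subs = []
        for i in range(6):
            t = np.sort(rng.uniform(0.5, 4.0, size=3))
            subs.append(SubjectRecord(i, float(rng.uniform(0.1, 0.4)), 4.5,
                                      int(rng.integers(0, 3)), t,
                                      142 + rng.normal(size=3) * 10))
        cfg = QMCConfig(S=64, scramble_seed=3)
        ref = total_loglik(spec_a, subs, truth_pv_a, cfg, delayed_entry=True)
        ev = LikelihoodEvaluator(spec_a, subs, cfg, delayed_entry=True)
        assert ev.total(truth_pv_a.flatten()) == pytest.approx(ref, rel=1e-5)

    def test_no_nan_for_moderate_predictors(self, spec_a, data_a):
        rng = np.random.default_rng(0)
        ev = LikelihoodEvaluator(spec_a, data_a[:10], QMCConfig(S=64, scramble_seed=0))
        for _ in range(5):
            theta = rng.normal(scale=0.5, size=spec_a.n_params)
            theta[0] += 142
            assert np.isfinite(ev.total(theta))
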