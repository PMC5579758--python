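"""Mixed-effects layer: parameter assembly, likelihoods, EBEs, fitting."""

import math

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import norm

import cd4recon as c
from cd4recon import _batch
from cd4recon.population import PARAM_NAMES, _mvn_logpdf, _safe_chol


def make_subject(times, cd4, age=1110.0, flags=None, sid="T1"):
    return c.SubjectRecord(sid, age, flags or {}, np.asarray(times, float),
                           np.asarray(cd4, float))


def predict_times(params, age, times):
    arrays = {n: np.array([getattr(params, n)]) for n in _batch.PARAM_ORDER}
    return _batch.solve_blocks(arrays, [age], [np.asarray(times, float)], [1])[0][:, 0]


class TestIndividualParameters:
    def test_identity_with_zero_eta(self, pop_truth):
        sp = c.individual_parameters(pop_truth, [], {}, np.zeros(6))
        for name, want in zip(PARAM_NAMES, pop_truth.theta):
            assert getattr(sp, name) == pytest.approx(want)
        assert sp.cp == 1.0 and sp.cd == 1.0

    def test_published_alemtuzumab_example(self):
        """A -82.8% effect on X0 turns 178 cells/uL into 30.6 cells/uL."""
        theta = np.array([0.216, 0.477, 0.207, 178.0, 133.0, 9.66])
        eff = [c.CovariateEffect("alemtuzumab", "x0", -0.828)]
        sp = c.individual_parameters(theta, eff, {"alemtuzumab": 1}, np.zeros(6))
        assert sp.x0 == pytest.approx(30.6, abs=0.02)

    def test_effects_compose_multiplicatively_any_order(self, pop_truth):
        e1 = c.CovariateEffect("a", "x0", -0.5)
        e2 = c.CovariateEffect("b", "x0", 0.25)
        flags = {"a": 1, "b": 1}
        sp12 = c.individual_parameters(pop_truth, [e1, e2], flags, np.zeros(6))
        sp21 = c.individual_parameters(pop_truth, [e2, e1], flags, np.zeros(6))
        assert sp12.x0 == pytest.approx(pop_truth.theta[3] * 0.5 * 1.25)
        assert sp12.x0 == pytest.approx(sp21.x0)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            c.CovariateEffect("a", "not_a_parameter", 0.1)
        with pytest.raises(ValueError):
            c.CovariateEffect("a", "x0", -1.0)  # parameter would vanish

    def test_missing_covariate_flag_is_error(self, pop_truth):
        eff = [c.CovariateEffect("gvhd", "x0", 0.28)]
        with pytest.raises(KeyError):
            c.individual_parameters(pop_truth, eff, {}, np.zeros(6))


class TestObservationLoglik:
    def test_zero_residual_closed_form(self, pop_truth):
        sp = c.individual_parameters(pop_truth, [], {}, np.zeros(6))
        times = [30.0, 90.0, 180.0, 365.0]
        on_curve = predict_times(sp, 1110.0, times)
        subject = make_subject(times, on_curve)
        sigma2 = 0.219
        got = c.observation_loglik(subject, sp, sigma2)
        assert got == pytest.approx(-2.0 * math.log(2 * math.pi * sigma2), rel=1e-6)

    def test_matches_per_point_normal_oracle(self, pop_truth):
        sp = c.individual_parameters(pop_truth, [], {}, np.zeros(6))
        times = [20.0, 100.0, 300.0, 700.0, 1200.0]
        pred = predict_times(sp, 900.0, times)
        rng = np.random.default_rng(3)
        dv = np.exp(np.log(pred) + rng.normal(0, 0.4, len(times)))
        subject = make_subject(times, dv, age=900.0)
        want = norm.logpdf(np.log(dv), np.log(pred), math.sqrt(0.219)).sum()
        assert c.observation_loglik(subject, sp, 0.219) == pytest.approx(
            want, abs=1e-4)

    def test_halving_variance_with_zero_residuals(self, pop_truth):
        sp = c.individual_parameters(pop_truth, [], {}, np.zeros(6))
        times = [30.0, 90.0, 180.0]
        subject = make_subject(times, predict_times(sp, 1110.0, times))
        gain = (c.observation_loglik(subject, sp, 0.1)
                - c.observation_loglik(subject, sp, 0.2))
        assert gain == pytest.approx(1.5 * math.log(2), rel=1e-5)


class TestMarginalLikelihood:
    def test_point_mass_prior_limit(self, pop_truth):
        """Omega -> 0: the marginal collapses to the likelihood at eta = 0."""
        sp = c.individual_parameters(pop_truth, [], {}, np.zeros(6))
        times = [30.0, 90.0, 365.0]
        rng = np.random.default_rng(5)
        dv = np.exp(np.log(predict_times(sp, 1110.0, times)) + rng.normal(0, 0.3, 3))
        subject = make_subject(times, dv)
        tiny = c.PopulationParameters(pop_truth.theta, np.eye(6) * 1e-10, 0.219)
        neg2ll, est = c.marginal_neg2ll_is(subject, tiny, n_samples=3000, seed=1)
        assert neg2ll == pytest.approx(
            -2 * c.observation_loglik(subject, sp, 0.219), abs=0.05)

    def test_no_observations_returns_prior(self, pop_truth):
        subject = make_subject([], [])
        neg2ll, est = c.marginal_neg2ll_is(subject, pop_truth, seed=0)
        assert neg2ll == 0.0
        assert np.allclose(est.eta_mean, 0.0)
        assert np.allclose(est.eta_cov, pop_truth.omega)

    def test_matches_grid_quadrature_with_two_random_effects(self, pop_truth):
        """2 free random effects (d0, x0): IS within 0.1 of a 60x60 grid."""
        var = np.full(6, 1e-12)
        var[1], var[3] = 0.5, 0.6  # d0 and x0 vary
        pop = c.PopulationParameters(pop_truth.theta, np.diag(var), 0.219)
        sp = c.individual_parameters(
            pop_truth, [], {}, np.array([0.0, 0.4, 0.0, -0.5, 0.0, 0.0]))
        times = np.array([30.0, 60.0, 120.0, 240.0, 420.0, 700.0])
        rng = np.random.default_rng(11)
        dv = np.exp(np.log(predict_times(sp, 1110.0, times))
                    + rng.normal(0, math.sqrt(0.219), len(times)))
        subject = make_subject(times, dv)

        # quadrature oracle over the two active dimensions
        g1 = np.linspace(-4.5 * math.sqrt(var[1]), 4.5 * math.sqrt(var[1]), 60)
        g3 = np.linspace(-4.5 * math.sqrt(var[3]), 4.5 * math.sqrt(var[3]), 60)
        G1, G3 = np.meshgrid(g1, g3, indexing="ij")
        K = G1.size
        eta = np.zeros((6, K))
        eta[1], eta[3] = G1.ravel(), G3.ravel()
        values = np.exp(np.log(pop.theta)[:, None] + eta)
        arrays = {n: values[i] for i, n in enumerate(PARAM_NAMES)}
        arrays["cp"] = np.ones(K)
        arrays["cd"] = np.ones(K)
        pred = _batch.solve_blocks(arrays, [1110.0], [times], [K])[0]
        loglik = (-0.5 * len(times) * math.log(2 * math.pi * 0.219)
                  - 0.5 * ((np.log(dv)[:, None] - np.log(pred)) ** 2).sum(0) / 0.219)
        logprior = (norm.logpdf(G1.ravel(), 0, math.sqrt(var[1]))
                    + norm.logpdf(G3.ravel(), 0, math.sqrt(var[3])))
        dA = (g1[1] - g1[0]) * (g3[1] - g3[0])
        oracle = -2.0 * (logsumexp(loglik + logprior) + math.log(dA))

        neg2ll, _ = c.marginal_neg2ll_is(subject, pop, n_samples=4000, seed=2)
        assert neg2ll == pytest.approx(oracle, abs=0.1)

    def test_reproducible_given_seed(self, pop_truth, small_cohort):
        dataset, _ = small_cohort
        subject = dataset.subjects[0]
        a = c.marginal_neg2ll_is(subject, pop_truth, n_samples=300, seed=9)
        b = c.marginal_neg2ll_is(subject, pop_truth, n_samples=300, seed=9)
        assert a[0] == b[0]
        assert np.array_equal(a[1].eta_mean, b[1].eta_mean)

    def test_spread_shrinks_with_sample_size(self, pop_truth, small_cohort):
        """IS noise scales roughly like 1/sqrt(n_samples)."""
        dataset, _ = small_cohort
        subject = next(s for s in dataset.subjects if 3 <= s.n_obs <= 7)
        reps = lambda K: np.array([
            c.marginal_neg2ll_is(subject, pop_truth, n_samples=K, seed=s)[0]
            for s in range(10)])
        sd_small = np.std(reps(200), ddof=1)
        sd_big = np.std(reps(800), ddof=1)
        assert sd_big < sd_small
        assert 1.2 < sd_small / sd_big < 4.0


class TestEmpiricalBayes:
    def test_low_noise_recovers_true_eta(self, pop_truth):
        # dense sampling across the thymic transition window (days 10-260) is
        # what identifies the recovery-steepness random effect
        eta_true = np.array([0.3, -0.4, 0.2, 0.5, -0.3, 0.2])
        sp = c.individual_parameters(pop_truth, [], {}, eta_true)
        times = np.concatenate([np.arange(10.0, 260.0, 10.0),
                                [300, 365, 450, 550, 700, 900, 1100, 1400]])
        dv = predict_times(sp, 1110.0, times)
        subject = make_subject(times, dv)
        pop = c.PopulationParameters(pop_truth.theta, pop_truth.omega, 1e-4)
        est = c.empirical_bayes(subject, pop, n_samples=300, seed=3)
        assert np.max(np.abs(est.eta_mean - eta_true)) < 0.05

    def test_posterior_contracts_with_more_data(self, pop_truth):
        eta_true = np.array([0.2, 0.1, -0.1, -0.4, 0.1, 0.0])
        sp = c.individual_parameters(pop_truth, [], {}, eta_true)
        all_times = np.linspace(20, 1400, 24)
        rng = np.random.default_rng(8)
        dv = np.exp(np.log(predict_times(sp, 1110.0, all_times))
                    + rng.normal(0, math.sqrt(0.219), len(all_times)))
        prev = None
        for n in (4, 12, 24):
            subject = make_subject(all_times[:n], dv[:n])
            est = c.empirical_bayes(subject, pop_truth, n_samples=600, seed=4)
            total_var = float(np.trace(est.eta_cov))
            if prev is not None:
                assert total_var <= prev * 1.1  # slack for MC noise
            prev = total_var


class TestFitPopulation:
    def test_requires_two_subjects(self, pop_truth):
        ds = c.Dataset([make_subject([30.0], [100.0])])
        with pytest.raises(ValueError):
            c.fit_population(ds, pop_truth)

    def test_small_fit_mechanics_and_determinism(self, pop_truth, small_cohort):
        dataset, _ = small_cohort
        settings = c.FitSettings(n_samples=80, max_iter=6)
        fit1 = c.fit_population(dataset, pop_truth, settings=settings, seed=5)
        fit2 = c.fit_population(dataset, pop_truth, settings=settings, seed=5)
        assert np.array_equal(fit1.pop.theta, fit2.pop.theta)
        assert fit1.trace == fit2.trace
        assert np.all(fit1.pop.theta > 0)
        assert np.linalg.eigvalsh(fit1.pop.omega).min() > -1e-10
        assert np.isfinite(fit1.objective)
        assert fit1.seed == 5 and fit1.n_iter == len(fit1.trace)


class TestBootstrap:
    def test_zero_variability_gives_tiny_ses(self, pop_truth):
        pop0 = c.PopulationParameters(pop_truth.theta, np.eye(6) * 1e-9, 1e-6)
        spec = c.CohortSpec(n_subjects=16, horizon_days=730.0)
        sk = c.sample_demographics(spec, seed=3)
        sch = c.sample_schedule(spec, len(sk), seed=3)
        ds, _ = c.simulate_dataset(pop0, [], sk, sch, seed=3)
        out = c.bootstrap_se(ds, pop0, n_boot=6, seed=1,
                             settings=c.FitSettings(n_samples=60, max_iter=2,
                                                    accelerate=False))
        assert out["n_used"] >= 4
        assert np.all(out["theta_se"] / pop0.theta < 0.02)

    def test_ses_shrink_with_cohort_size(self, pop_truth):
        ses = {}
        for n in (25, 100):
            spec = c.CohortSpec(n_subjects=n, horizon_days=1095.0)
            sk = c.sample_demographics(spec, seed=6)
            sch = c.sample_schedule(spec, len(sk), seed=6)
            ds, _ = c.simulate_dataset(pop_truth, [], sk, sch, seed=6)
            out = c.bootstrap_se(ds, pop_truth, n_boot=10, seed=2,
                                 settings=c.FitSettings(n_samples=60, max_iter=2,
                                                        accelerate=False))
            ses[n] = out["theta_se"] / pop_truth.theta
        ratio = np.median(ses[25] / ses[100])
        assert 1.2 < ratio < 4.0  # ~2 expected from 1/sqrt(n)

    def test_n_boot_validation(self, pop_truth, small_cohort):
        with pytest.raises(ValueError):
            c.bootstrap_se(small_cohort[0], pop_truth, n_boot=1)
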