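"""Synthetic cohort generator: demographics, schedules, simulated observations."""

import math

import numpy as np
import pytest

import cd4recon as c
from cd4recon import _batch


class TestDemographics:
    def test_band_and_flag_frequencies(self):
        spec = c.CohortSpec(n_subjects=10_000)
        frame = c.sample_demographics(spec, seed=1)
        frac_infant = np.mean(frame["age_at_hsct"] < 365.0)
        assert frac_infant == pytest.approx(0.16, abs=0.01)
        assert frame["alemtuzumab"].mean() == pytest.approx(0.50, abs=0.01)
        assert frame["gvhd"].mean() == pytest.approx(0.32, abs=0.012)
        assert frame["age_at_hsct"].max() <= 18 * 365.0
        assert frame["age_at_hsct"].min() >= 30.0

    def test_deterministic_given_seed(self):
        spec = c.CohortSpec(n_subjects=50)
        a = c.sample_demographics(spec, seed=9)
        b = c.sample_demographics(spec, seed=9)
        assert a.equals(b)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            c.CohortSpec(age_bands=((30.0, 365.0, 0.5), (365.0, 730.0, 0.2)))
        with pytest.raises(ValueError):
            c.CohortSpec(prevalences={"x": 1.5})
        with pytest.raises(ValueError):
            c.CohortSpec(horizon_days=-1.0)


class TestSchedule:
    def test_count_distribution(self):
        spec = c.CohortSpec()
        schedules = c.sample_schedule(spec, 10_000, seed=2)
        counts = np.array([len(t) for t in schedules])
        assert counts.min() >= 1 and counts.max() <= 43
        assert abs(np.median(counts) - 8) <= 1

    def test_times_sorted_within_window(self):
        spec = c.CohortSpec()
        schedules = c.sample_schedule(spec, 500, seed=3)
        for t in schedules:
            assert t[0] >= 14.0 and t[-1] <= spec.horizon_days
            assert np.all(np.diff(t) >= spec.min_spacing_days - 1e-9)

    def test_sampling_denser_in_first_year(self):
        spec = c.CohortSpec()
        schedules = c.sample_schedule(spec, 10_000, seed=4)
        times = np.concatenate(schedules)
        assert np.mean(times < 365.0) >= 0.5


class TestSimulateDataset:
    def test_noise_free_observations_lie_on_typical_curve(self, pop_truth):
        pop0 = c.PopulationParameters(pop_truth.theta, np.eye(6) * 1e-14, 1e-14)
        spec = c.CohortSpec(n_subjects=10, horizon_days=1095.0)
        sk = c.sample_demographics(spec, seed=5)
        sch = c.sample_schedule(spec, len(sk), seed=5)
        ds, truth = c.simulate_dataset(pop0, [], sk, sch, seed=5)
        sp = c.individual_parameters(pop_truth, [], {}, np.zeros(6))
        for s in ds.subjects:
            want = c.solve_trajectory(sp, s.age_at_hsct, s.times[-1] + 1,
                                      grid=s.times).concentrations[1:]
            assert np.allclose(s.cd4, want, rtol=1e-4)

    def test_residual_sd_matches_sigma(self, pop_truth):
        """Empirical SD of log(DV / X(t)) converges to sigma."""
        pop = c.PopulationParameters(pop_truth.theta, np.eye(6) * 1e-14, 0.219)
        spec = c.CohortSpec(n_subjects=400, horizon_days=1825.0)
        sk = c.sample_demographics(spec, seed=6)
        sch = c.sample_schedule(spec, len(sk), seed=6)
        ds, _ = c.simulate_dataset(pop, [], sk, sch, seed=6)
        arrays = {n: [] for n in _batch.PARAM_ORDER}
        sp = c.individual_parameters(pop_truth, [], {}, np.zeros(6))
        for n in _batch.PARAM_ORDER:
            arrays[n] = np.full(len(ds.subjects), getattr(sp, n))
        preds = _batch.solve_blocks(arrays, [s.age_at_hsct for s in ds.subjects],
                                    [s.times for s in ds.subjects],
                                    [1] * len(ds.subjects))
        resid = np.concatenate([
            np.log(s.cd4) - np.log(p[:, 0]) for s, p in zip(ds.subjects, preds)])
        assert len(resid) > 2500
        assert np.std(resid) == pytest.approx(math.sqrt(0.219), rel=0.05)

    def test_covariate_effect_applied_to_flagged_subjects(self, pop_truth):
        pop = c.PopulationParameters(pop_truth.theta, np.eye(6) * 1e-14, 1e-14)
        eff = [c.CovariateEffect("alemtuzumab", "x0", -0.828)]
        spec = c.CohortSpec(n_subjects=40, horizon_days=365.0)
        sk = c.sample_demographics(spec, seed=7)
        sch = c.sample_schedule(spec, len(sk), seed=7)
        ds, truth = c.simulate_dataset(pop, eff, sk, sch, seed=7)
        flagged = truth.merge(sk[["subject_id", "alemtuzumab"]], on="subject_id")
        x0 = flagged.set_index("alemtuzumab")["x0"]
        assert x0.loc[1].mean() == pytest.approx(168.0 * 0.172, rel=1e-6)
        assert x0.loc[0].mean() == pytest.approx(168.0, rel=1e-6)

    def test_truth_sidecar_consistent(self, small_cohort, pop_truth):
        dataset, truth = small_cohort
        row = truth.iloc[0]
        eta = row[[f"eta_{n}" for n in c.PARAM_NAMES]].to_numpy(float)
        assert row["lambda0"] == pytest.approx(
            pop_truth.theta[0] * math.exp(eta[0]), rel=1e-10)

    def test_deterministic_and_positive(self, pop_truth):
        spec = c.CohortSpec(n_subjects=12, horizon_days=730.0)
        sk = c.sample_demographics(spec, seed=8)
        sch = c.sample_schedule(spec, len(sk), seed=8)
        a, _ = c.simulate_dataset(pop_truth, [], sk, sch, seed=8)
        b, _ = c.simulate_dataset(pop_truth, [], sk, sch, seed=8)
        for sa, sb in zip(a.subjects, b.subjects):
            assert np.array_equal(sa.cd4, sb.cd4)
            assert np.all(sa.cd4 > 0)
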