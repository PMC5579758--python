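"""Single-compartment reconstitution model: rates, solver, derived summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import cd4recon as c
from cd4recon.defaults import typical_parameters
from cd4recon.kinetics import _rhs


def table1(**kw):
    base = dict(lambda0=0.216, d0=0.477, p0=0.207, x0=168.0,
                lambda_h=133.0, lambda_r=9.66)
    base.update(kw)
    return c.StructuralParameters(**base)


class TestThymicRecovery:
    def test_zero_at_transplant(self):
        assert c.thymic_recovery(0.0, 133.0, 9.66) == 0.0

    def test_limit_one(self):
        assert c.thymic_recovery(1e6, 133.0, 9.66) == pytest.approx(1.0)

    def test_closed_form_at_lambda_h(self):
        # (1 - e^-2) / 2 when t = lambda_h
        assert c.thymic_recovery(133.0, 133.0, 9.66) == pytest.approx(
            (1 - np.exp(-2)) / 2, rel=1e-12)

    def test_overflow_safe(self):
        with np.errstate(over="raise"):
            v = c.thymic_recovery(1.0, 133.0, 1e6)
        assert 0.0 <= v < 1e-10

    @settings(max_examples=50, deadline=None)
    @given(t1=st.floats(0, 2000), t2=st.floats(0, 2000),
           lh=st.floats(20, 400), lr=st.floats(0.5, 50))
    def test_monotone_in_time(self, t1, t2, lh, lr):
        lo, hi = sorted([t1, t2])
        assert c.thymic_recovery(lo, lh, lr) <= c.thymic_recovery(hi, lh, lr) + 1e-12

    def test_earlier_recovery_for_smaller_lambda_h(self):
        t = np.linspace(1, 600, 50)
        assert np.all(c.thymic_recovery(t, 90.0, 9.66)
                      >= c.thymic_recovery(t, 180.0, 9.66))


class TestRates:
    def test_proliferation_at_reference_density(self):
        age = 1110.0
        n = c.expected_total_cd4(age)
        assert c.proliferation_rate(n, age, 0.207) == pytest.approx(
            0.207 * c.ki67_fraction(age), rel=1e-12)

    def test_proliferation_low_density_limit(self):
        age = 1110.0
        got = c.proliferation_rate(1e-6, age, 0.207, cp=1.0)
        assert got == pytest.approx(0.207 * c.ki67_fraction(age) * np.e, rel=1e-4)

    def test_loss_at_reference_density(self):
        age = 1110.0
        n = c.expected_total_cd4(age)
        assert c.loss_rate(n, age, 0.477) == pytest.approx(
            0.477 * c.ki67_fraction(age), rel=1e-12)

    def test_loss_low_density_limit(self):
        age = 1110.0
        got = c.loss_rate(1e-6, age, 0.477, cd=1.0)
        assert got == pytest.approx(0.477 * c.ki67_fraction(age) / np.e, rel=1e-4)

    def test_direct_evaluation_against_reference_oracle(self):
        # p and d at X=168, age 1110 from the printed formulas
        x, age = 168.0, 1110.0
        ratio = x / c.expected_total_cd4(age)
        y = c.ki67_fraction(age)
        assert c.proliferation_rate(x, age, 0.207) == pytest.approx(
            0.207 * y * np.exp(1 - ratio), rel=1e-12)
        assert c.loss_rate(x, age, 0.477) == pytest.approx(
            0.477 * y * np.exp(ratio - 1), rel=1e-12)

    def test_monotone_in_density(self):
        age = 500.0
        xs = np.linspace(10, 4000, 40)
        p = c.proliferation_rate(xs, age, 0.207)
        d = c.loss_rate(xs, age, 0.477)
        assert np.all(np.diff(p) < 0) and np.all(np.diff(d) > 0)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError):
            c.proliferation_rate(0.0, 100.0, 0.2)
        with pytest.raises(ValueError):
            c.loss_rate(-5.0, 100.0, 0.4)


class TestSolveTrajectory:
    def test_initial_condition_and_positivity(self):
        traj = c.solve_trajectory(table1(), 1110.0, 730.0)
        assert traj.concentrations[0] == pytest.approx(168.0)
        assert np.all(traj.concentrations > 0)

    def test_pure_decay_without_input_or_proliferation(self):
        traj = c.solve_trajectory(table1(lambda0=0.0, p0=0.0), 1110.0, 365.0)
        assert np.all(np.diff(traj.concentrations) < 0)

    def test_pure_accumulation_matches_quadrature(self):
        """With p0 = d0 = 0 the ODE reduces to X = x0 + int lambda(s) ds."""
        params = table1(p0=0.0, d0=0.0)
        age0, t_end = 1110.0, 365.0
        traj = c.solve_trajectory(params, age0, t_end, grid=[0.0, t_end])
        integral, _ = quad(
            lambda s: params.lambda0 * c.thymic_output_for_age(age0 + s)
            * c.thymic_recovery(s, params.lambda_h, params.lambda_r),
            0.0, t_end, limit=200)
        assert traj.concentrations[-1] == pytest.approx(168.0 + integral, rel=1e-3)

    def test_solver_tolerance_halving(self):
        grid = np.array([0.0, 90.0, 365.0, 1000.0])
        a = c.solve_trajectory(table1(), 1110.0, 1000.0, grid=grid)
        b = c.solve_trajectory(table1(), 1110.0, 1000.0, grid=grid,
                               rtol=5e-9, atol=5e-7)
        assert np.allclose(a.concentrations, b.concentrations, rtol=1e-3)

    def test_fixed_step_oracle_agreement(self):
        """Production solver vs an independent fixed-step RK4 at h=0.05 day."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            scale = np.exp(rng.normal(0, 0.4, 6))
            params = c.StructuralParameters(
                0.216 * scale[0], 0.477 * scale[1], 0.207 * scale[2],
                168.0 * scale[3], 133.0 * scale[4], 9.66 * scale[5])
            age0 = float(rng.uniform(200, 4000))
            t_end = 200.0
            h = 0.05
            x = params.x0
            t = 0.0
            for _step in range(int(t_end / h)):
                k1 = _rhs(t, x, params, age0, c.AgeReferenceConstants())
                k2 = _rhs(t + h / 2, x + h / 2 * k1, params, age0, c.AgeReferenceConstants())
                k3 = _rhs(t + h / 2, x + h / 2 * k2, params, age0, c.AgeReferenceConstants())
                k4 = _rhs(t + h, x + h * k3, params, age0, c.AgeReferenceConstants())
                x = x + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                t += h
            traj = c.solve_trajectory(params, age0, t_end, grid=[0.0, t_end])
            assert traj.concentrations[-1] == pytest.approx(float(x), rel=1e-3)

    def test_trajectory_invariants(self):
        with pytest.raises(ValueError):
            c.Trajectory([0.0, 1.0], [10.0, -1.0], 100.0)
        with pytest.raises(ValueError):
            c.Trajectory([1.0, 2.0, 1.5], [10.0, 11.0, 12.0], 100.0)


class TestTimeToThreshold:
    def test_crossing_at_start(self):
        assert c.time_to_threshold(table1(), 1110.0, 168.0) == 0.0

    def test_not_reached_sentinel(self):
        assert np.isnan(c.time_to_threshold(table1(), 1110.0, 1e6,
                                            horizon=365.0))

    def test_absolute_crossing_bracketed_on_curve(self):
        t500 = c.time_to_threshold(table1(x0=30.6), 1110.0, 500.0)
        traj = c.solve_trajectory(table1(x0=30.6), 1110.0, t500 + 2,
                                  grid=[0.0, t500 - 1.0, t500 + 1.0])
        assert traj.concentrations[1] < 500.0 < traj.concentrations[2]

    def test_relative_crossing_definition(self):
        t90 = c.time_to_threshold(table1(x0=30.6), 1110.0, 0.9, relative=True)
        traj = c.solve_trajectory(table1(x0=30.6), 1110.0, t90 + 2,
                                  grid=[0.0, t90])
        assert traj.concentrations[-1] == pytest.approx(
            0.9 * c.expected_total_cd4(1110.0 + t90), rel=1e-3)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            c.time_to_threshold(table1(), 1110.0, 0.0)


class TestThymicOutputCurve:
    def test_zero_at_transplant(self):
        assert c.thymic_output_curve(table1(), 1110.0, [0.0])[0] == 0.0

    def test_late_plateau_equals_age_curve(self):
        t = 1500.0
        got = c.thymic_output_curve(table1(), 1110.0, [t])[0]
        want = 0.216 * c.thymic_output_for_age(1110.0 + t)
        assert got == pytest.approx(want, rel=0.01)

    def test_recovery_midpoint_near_137_days(self):
        # root of Delta(t) = 1/2 with the published lambda_h, lambda_r
        from scipy.optimize import brentq

        mid = brentq(lambda t: c.thymic_recovery(t, 133.0, 9.66) - 0.5, 50, 400)
        assert mid == pytest.approx(137.05, abs=0.5)

    def test_unimodal(self):
        grid = np.linspace(0, 2500, 500)
        curve = c.thymic_output_curve(table1(), 1110.0, grid)
        peak = np.argmax(curve)
        assert 0 < peak < len(grid) - 1
        assert np.all(np.diff(curve[:peak]) > 0)
        assert np.all(np.diff(curve[peak + 5:]) < 0)


class TestMeanLifespan:
    def test_full_occupancy_closed_form(self):
        got = c.mean_lifespan(365.0, 0.477, occupancy=1.0)
        assert got == pytest.approx(1.0 / (0.477 * c.ki67_fraction(365.0)),
                                    rel=1e-12)

    def test_increases_with_age(self):
        assert c.mean_lifespan(3650.0, 0.477) > c.mean_lifespan(365.0, 0.477)

    def test_default_occupancy_values(self):
        # lifespans at the long-run 90% occupancy: ~128 d at 1 y, ~310 d at 10 y
        assert c.mean_lifespan(365.0, 0.477) == pytest.approx(127.8, rel=1e-3)
        assert c.mean_lifespan(3650.0, 0.477) == pytest.approx(310.4, rel=1e-3)


def test_long_run_tracks_ninety_percent_of_reference():
    """With calibrated defaults the typical trajectory stabilizes near 90% of
    the age-expected concentration."""
    traj = c.solve_trajectory(typical_parameters(), 1110.0, 2557.0,
                              grid=np.linspace(0, 2557, 200))
    ratio = traj.concentrations / c.expected_total_cd4(1110.0 + traj.times)
    late = ratio[traj.times > 1500]
    assert np.all((late > 0.85) & (late < 1.0))
    assert np.std(np.diff(late)) < 0.01
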