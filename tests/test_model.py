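"""Core dynamical system: Hill kinetics, derivatives, Euler integration."""

import numpy as np
import pytest

from lysedyn import (ConstantInduction, ConvergenceWarning, IntegrationError,
                     ModelParams, PopulationState, SquareWaveInduction,
                     beta_of_ahl, crash_summary, hill, integrate, rhs)
from lysedyn.analytic import fraction_curve


def logistic(t, x0, gamma0, rho_s):
    e = np.exp(gamma0 * t)
    return rho_s * x0 * e / (rho_s + x0 * (e - 1.0))


class TestHill:
    @pytest.mark.parametrize(
        "value,threshold,coef,expected",
        [
            (0.0, 3.29, 4.46, 0.0),
            (3.29, 3.29, 4.46, 0.5),
            (19.0, 19.0, 1.0, 0.5),
            (100.0, 19.0, 1.0, 100.0 / 119.0),
        ],
    )
    def test_values(self, value, threshold, coef, expected):
        assert hill(value, threshold, coef) == pytest.approx(expected, rel=1e-12)

    def test_monotone_and_saturating(self):
        v = np.linspace(0, 50, 200)
        h = hill(v, 3.29, 4.46)
        assert np.all(np.diff(h) > 0)
        assert hill(1e12, 3.29, 4.46) == pytest.approx(1.0, abs=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hill(-1.0, 3.29, 4.46)
        with pytest.raises(ValueError):
            hill(1.0, 0.0, 4.46)


class TestBetaOfAhl:
    def test_zero_and_half_max(self, params):
        assert beta_of_ahl(0.0, params) == 0.0
        assert beta_of_ahl(19.0, params) == pytest.approx(3.05, rel=1e-12)

    def test_direct_evaluation(self, params):
        assert beta_of_ahl(100.0, params) == pytest.approx(6.1 * 100 / 119, rel=1e-12)

    def test_negative_rejected(self, params):
        with pytest.raises(ValueError):
            beta_of_ahl(-5.0, params)


class TestRhs:
    def test_empty_culture(self, params):
        dx, dy, dp = rhs(PopulationState(0, 0, 0), params, ahl=100.0)
        assert dx == 0 and dy == 0
        assert dp == pytest.approx(beta_of_ahl(100.0, params))

    def test_at_carrying_capacity_no_toxin(self, params):
        st = PopulationState(params.rho_s / 2, params.rho_s / 2, 0.0)
        dx, dy, dp = rhs(st, params, ahl=50.0)
        assert dx == pytest.approx(0.0, abs=1e-15)
        assert dy == pytest.approx(0.0, abs=1e-15)
        assert dp == pytest.approx(beta_of_ahl(50.0, params))

    def test_hill_midpoint_lysis(self, params):
        st = PopulationState(0.01, 0.0, params.K)
        dx, _, _ = rhs(st, params, ahl=0.0)
        gamma = params.gamma0 * (1 - 0.01 / params.rho_s)
        assert dx == pytest.approx((gamma - params.alpha0 / 2) * 0.01, rel=1e-12)

    def test_positive_part_readings_differ_when_lysis_dominates(self, params):
        st = PopulationState(params.rho_s, 0.0, 10 * params.K)  # gamma=0, alpha~alpha0
        _, _, dp_net = rhs(st, params, 100.0, positive_part="net_growth")
        _, _, dp_g = rhs(st, params, 100.0, positive_part="growth")
        assert dp_net == dp_g  # both clamps give zero dilution here
        st2 = PopulationState(0.01, 0.0, 10 * params.K)  # gamma>0 but alpha>gamma...
        _, _, a = rhs(st2, params.replace(alpha0=5.0), 100.0, positive_part="net_growth")
        _, _, b = rhs(st2, params.replace(alpha0=5.0), 100.0, positive_part="growth")
        assert a > b  # growth-clamp keeps diluting, net-growth clamp does not


class TestIntegrate:
    def test_logistic_oracle_without_lysis(self, params):
        p = params.replace(alpha0=0.0)
        traj = integrate(p, ConstantInduction(100.0), PopulationState(0.01, 0, 0),
                         t_end=8.0, dt=1e-3)
        expected = logistic(traj.times, 0.01, p.gamma0, p.rho_s)
        assert np.max(np.abs(traj.x - expected)) < 5e-4

    def test_no_induction_means_no_toxin(self, params):
        p = params.replace(beta0=0.0)
        traj = integrate(p, ConstantInduction(100.0), PopulationState(0.01, 0, 0),
                         t_end=10.0)
        assert np.all(traj.p == 0.0)
        expected = logistic(traj.times, 0.01, p.gamma0, p.rho_s)
        assert np.max(np.abs(traj.x - expected)) < 5e-4

    def test_extinction_is_absorbing(self, params):
        traj = integrate(params, ConstantInduction(100.0),
                         PopulationState(0.0, 1e-4, 0.0), t_end=5.0)
        assert np.all(traj.x == 0.0)
        assert np.all(traj.fraction_mutant == 1.0)

    def test_mutant_fraction_non_decreasing(self, params, init_state):
        traj = integrate(params, SquareWaveInduction(100.0, 6.0, 1.0),
                         init_state, t_end=48.0, dt=2e-3)
        f = traj.fraction_mutant
        assert np.all(np.diff(f) >= -1e-12)

    def test_toxin_production_bound(self, params, init_state):
        traj = integrate(params, ConstantInduction(1000.0), init_state, t_end=24.0)
        assert np.all(traj.p <= params.beta0 * traj.times + 1e-9)

    def test_density_scale_equivariance_of_fraction(self, params):
        # scaling x0, y0, rho_s together leaves f(t) unchanged
        t_end, dt = 12.0, 1e-3
        a = integrate(params, ConstantInduction(100.0),
                      PopulationState.from_total(0.01, 1e-4), t_end, dt)
        p2 = params.replace(rho_s=10 * params.rho_s)
        b = integrate(p2, ConstantInduction(100.0),
                      PopulationState.from_total(0.1, 1e-4), t_end, dt)
        assert np.allclose(a.fraction_mutant, b.fraction_mutant, rtol=1e-6, atol=1e-12)

    def test_euler_first_order_convergence(self, params):
        # global error vs the logistic closed form scales ~ dt^1
        p = params.replace(alpha0=0.0)
        dts = np.array([4e-3, 2e-3, 1e-3, 5e-4])
        errs = []
        for dt in dts:
            traj = integrate(p, ConstantInduction(0.0), PopulationState(0.01, 0, 0),
                             t_end=6.0, dt=dt)
            ref = logistic(traj.times, 0.01, p.gamma0, p.rho_s)
            errs.append(np.max(np.abs(traj.x - ref)))
        slope = np.polyfit(np.log(dts), np.log(errs), 1)[0]
        assert 0.8 < slope < 1.2

    def test_trajectory_fraction_matches_quadrature_solution(self, params, init_state):
        # the Euler trajectory and the quadrature closed form agree to within
        # the integrator's first-order error, which shrinks linearly with dt
        errs = {}
        for dt in (1e-3, 5e-4, 1.25e-4):
            traj = integrate(params, ConstantInduction(100.0), init_state,
                             t_end=24.0, dt=dt)
            rel = np.abs(fraction_curve(traj) - traj.fraction_mutant) / \
                np.maximum(traj.fraction_mutant, 1e-30)
            errs[dt] = np.max(rel)
        assert errs[1e-3] < 1e-2
        assert errs[5e-4] < 0.6 * errs[1e-3]  # first-order shrinkage
        assert errs[1.25e-4] < 1e-3

    def test_convergence_warning_on_coarse_step(self, params, init_state):
        with pytest.warns(ConvergenceWarning):
            integrate(params, ConstantInduction(100.0), init_state,
                      t_end=24.0, dt=0.5, check_convergence=True)

    def test_fine_step_passes_convergence_check(self, params, init_state):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            integrate(params, ConstantInduction(100.0), init_state,
                      t_end=24.0, dt=1e-3, check_convergence=True)

    def test_nonfinite_state_raises_with_time(self):
        # a toxin level whose Hill power overflows produces NaN derivatives
        p = ModelParams(gamma0=1.0, rho_s=1.0, alpha0=1.0, K=1.0, n=4.46,
                        beta0=0.0, k=1.0, m=1.0, delta=0.0)
        with pytest.raises(IntegrationError, match="t ="):
            integrate(p, ConstantInduction(0.0),
                      PopulationState(0.5, 0, 1e200), t_end=1.0, dt=0.1)

    def test_invalid_grid_arguments(self, params, init_state):
        with pytest.raises(ValueError):
            integrate(params, ConstantInduction(0.0), init_state, t_end=1.0, dt=0.0)
        with pytest.raises(ValueError):
            integrate(params, ConstantInduction(0.0), init_state, t_end=0.0)


class TestCrashSummary:
    def test_induced_curve_has_crash(self, params, init_state):
        traj = integrate(params, ConstantInduction(100.0), init_state, t_end=24.0)
        cs = crash_summary(traj)
        assert cs is not None
        assert cs.peak_time < cs.trough_time
        assert 0 < cs.drop_percent < 100

    def test_uninduced_curve_has_none(self, params, init_state):
        traj = integrate(params, ConstantInduction(0.0), init_state, t_end=24.0)
        assert crash_summary(traj) is None


class TestExportRoundTrip:
    def test_trajectory_table_columns(self, params, init_state, tmp_path):
        traj = integrate(params, ConstantInduction(100.0), init_state, t_end=2.0,
                         dt=1e-2)
        path = tmp_path / "traj.tsv"
        traj.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == ["t_h", "ahl_nM", "x", "y", "p", "total",
                                    "fraction_mutant", "released_load"]
        assert len(df) == len(traj.times)
        assert df["released_load"].is_monotonic_increasing
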