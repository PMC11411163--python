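"""Parameter recovery and error handling for the fitting stack."""

import numpy as np
import pandas as pd
import pytest

from lysedyn import (EstimationError, FractionInductionModel, GrowthCurveModel,
                     HillInductionModel, MutantFractionModel, NoiseModel,
                     fraction_constant_alpha, generate_beta_calibration,
                     generate_plate_reader)

AHL_LEVELS = list(np.logspace(0, 3, 8))


class TestHillInductionFit:
    def test_exact_recovery_on_noiseless_data(self):
        df = generate_beta_calibration(6.1, 19.0, 1.0, AHL_LEVELS)
        res = HillInductionModel.from_dataframe(df).fit()
        assert res.params["beta0"] == pytest.approx(6.1, rel=1e-3)
        assert res.params["k"] == pytest.approx(19.0, rel=1e-3)
        assert res.params["m"] == pytest.approx(1.0, rel=1e-3)
        assert res.converged

    def test_underdetermined_designs_rejected(self):
        with pytest.raises(EstimationError):
            HillInductionModel([10.0, 100.0], [1.0, 2.0])
        with pytest.raises(EstimationError):
            HillInductionModel([50.0] * 6, [1, 1, 1, 1, 1, 1])

    def test_noisy_recovery_envelope(self):
        # 5% multiplicative noise: median estimates should sit near truth,
        # with spread comparable to the reference uncertainties (k 19+/-4, m 1.0+/-0.1)
        ks, ms = [], []
        for seed in range(100):
            df = generate_beta_calibration(6.1, 19.0, 1.0, AHL_LEVELS,
                                           noise_cv=0.05, seed=seed)
            r = HillInductionModel.from_dataframe(df).fit(n_starts=4, seed=seed)
            ks.append(r.params["k"])
            ms.append(r.params["m"])
        assert abs(np.median(ks) - 19.0) <= 4.0
        assert abs(np.median(ms) - 1.0) <= 0.1


class TestGrowthCurveFit:
    FREE = ("gamma0", "rho_s", "alpha0", "K", "n")

    def test_exact_recovery_on_noiseless_curves(self, params, no_noise):
        gcs = generate_plate_reader(params, [0.0, 10.0, 31.6, 100.0], f0=7e-5,
                                    replicates=1, noise=no_noise)
        start = params.replace(gamma0=1.2, alpha0=1.0, K=2.0, n=2.0)
        model = GrowthCurveModel(gcs, start, free=self.FREE,
                                 x0=0.01 * (1 - 7e-5), y0=0.01 * 7e-5)
        res = model.fit(n_starts=6, seed=0)
        truth = {"gamma0": 1.57, "rho_s": 0.33, "alpha0": 1.39, "K": 3.29, "n": 4.46}
        for name, v in truth.items():
            assert res.params[name] == pytest.approx(v, rel=1e-2), name

    def test_fitted_curves_recapitulate_crash_under_noise(self, params):
        from lysedyn import (ConstantInduction, PopulationState, crash_summary,
                             integrate)

        noise = NoiseModel(multiplicative_cv=0.03, additive_sd=0.0,
                           baseline_offset=0.0, seed=7)
        gcs = generate_plate_reader(params, [0.0, 10.0, 100.0], f0=7e-5,
                                    noise=noise, dt=5e-3)
        model = GrowthCurveModel(gcs, params.replace(gamma0=1.2, alpha0=1.0),
                                 free=self.FREE, x0=0.01 * (1 - 7e-5),
                                 y0=0.01 * 7e-5, dt=5e-3)
        res = model.fit(n_starts=4, seed=7)
        fitted = params.replace(**res.params)
        ref = crash_summary(integrate(params, ConstantInduction(10.0),
                                      PopulationState.from_total(0.01, 7e-5), 23.0))
        fit_cs = crash_summary(integrate(fitted, ConstantInduction(10.0),
                                         PopulationState.from_total(0.01, 7e-5), 23.0))
        assert fit_cs is not None
        assert fit_cs.peak_time == pytest.approx(ref.peak_time, abs=0.5)
        assert fit_cs.drop_percent == pytest.approx(ref.drop_percent, abs=10)

    def test_single_time_point_rejected(self, params):
        df = pd.DataFrame({
            "time_h": [0.0, 0.0, 0.0],
            "od600": [0.01, 0.011, 0.009],
            "ahl_nM": 100.0,
            "replicate": [0, 1, 2],
            "condition": "ahl_100",
        })
        with pytest.raises(EstimationError):
            GrowthCurveModel(df, params, free=self.FREE)

    def test_objective_invariant_to_record_order(self, params, no_noise, rng):
        gcs = generate_plate_reader(params, [10.0, 100.0], f0=7e-5,
                                    replicates=2, noise=no_noise, dt=5e-3)
        guess = {"gamma0": 1.3, "rho_s": 0.4, "alpha0": 1.2, "K": 3.0, "n": 3.0}
        m1 = GrowthCurveModel(gcs, params, free=self.FREE,
                              x0=0.01 * (1 - 7e-5), y0=0.01 * 7e-5, dt=5e-3)
        shuffled = gcs.data.sample(frac=1.0, random_state=42)
        shuffled = shuffled.sort_values(["condition", "replicate", "time_h"])
        m2 = GrowthCurveModel(shuffled, params, free=self.FREE,
                              x0=0.01 * (1 - 7e-5), y0=0.01 * 7e-5, dt=5e-3)
        t1 = m1._pack(guess)
        assert np.sum(m1._residuals(t1) ** 2) == pytest.approx(
            np.sum(m2._residuals(t1) ** 2), rel=1e-12)


class TestMutantFractionEstimate:
    def test_noiseless_recovery_of_stock_fraction(self, params, no_noise):
        gcs = generate_plate_reader(params, [100.0], f0=7e-5, replicates=3,
                                    noise=no_noise)
        est = MutantFractionModel(gcs, params).fit()
        assert est.f0 == pytest.approx(7e-5, rel=0.05)
        assert not est.flagged

    def test_zero_mutants_flagged_at_bound(self, params, no_noise):
        gcs = generate_plate_reader(params, [100.0], f0=0.0, replicates=1,
                                    noise=no_noise, duration=10.0, dt=5e-3)
        est = MutantFractionModel(gcs, params, dt=5e-3).fit()
        assert est.flagged
        assert est.f0 < 1e-6

    def test_half_mutant_culture_recovered(self, params, no_noise):
        gcs = generate_plate_reader(params, [100.0], f0=0.5, replicates=1,
                                    noise=no_noise, dt=5e-3)
        est = MutantFractionModel(gcs, params, dt=5e-3).fit()
        assert est.f0 == pytest.approx(0.5, rel=0.1)

    def test_estimate_monotone_in_true_fraction(self, params, no_noise):
        grid = [1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1]
        ests = []
        for f0 in grid:
            gcs = generate_plate_reader(params, [100.0], f0=f0, replicates=1,
                                        noise=no_noise, dt=5e-3)
            ests.append(MutantFractionModel(gcs, params, dt=5e-3).fit().f0)
        assert np.all(np.diff(ests) > 0)

    def test_multi_condition_input_rejected(self, params, no_noise):
        gcs = generate_plate_reader(params, [10.0, 100.0], f0=7e-5,
                                    replicates=1, noise=no_noise, duration=2.0,
                                    dt=1e-2)
        with pytest.raises(EstimationError):
            MutantFractionModel(gcs, params)


class TestFractionInductionFit:
    T_IND = np.array([0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0])

    def test_exact_recovery_on_noiseless_points(self):
        f = fraction_constant_alpha(self.T_IND, 2.1, 4.2e-5)
        res = FractionInductionModel(self.T_IND, f).fit()
        assert res.params["alpha"] == pytest.approx(2.1, rel=1e-6)
        assert res.params["f0"] == pytest.approx(4.2e-5, rel=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(EstimationError):
            FractionInductionModel([1.0, 2.0], [0.1, 0.2])
        with pytest.raises(EstimationError):
            FractionInductionModel([1, 2, 3], [0.1, 0.1, 0.1])
        with pytest.raises(EstimationError):
            FractionInductionModel([1, 2, 3], [0.1, 0.2, 1.0])

    def test_interval_coverage_under_logit_noise(self, rng):
        # nominal 95% t-intervals on the slope should cover near-nominally
        alpha_true, f0_true, sigma = 2.1, 4.2e-5, 0.3
        z_true = np.log(f0_true / (1 - f0_true)) + alpha_true * self.T_IND
        hits = 0
        n_mc = 200
        for _ in range(n_mc):
            z = z_true + rng.normal(0, sigma, size=z_true.shape)
            f = 1 / (1 + np.exp(-z))
            res = FractionInductionModel(self.T_IND, f).fit()
            lo, hi = res.conf_int["alpha"]
            hits += lo <= alpha_true <= hi
        assert 0.85 <= hits / n_mc <= 0.99


class TestBootstrap:
    def test_bootstrap_draws_concentrate_near_truth(self, params):
        noise = NoiseModel(multiplicative_cv=0.03, additive_sd=0.0,
                           baseline_offset=0.0, seed=11)
        gcs = generate_plate_reader(params, [10.0, 100.0], f0=7e-5,
                                    replicates=3, noise=noise, dt=5e-3)
        model = GrowthCurveModel(gcs, params, free=("gamma0", "rho_s"),
                                 x0=0.01 * (1 - 7e-5), y0=0.01 * 7e-5, dt=5e-3)
        draws = model.bootstrap(n_boot=8, seed=11)
        assert len(draws["gamma0"]) >= 6
        assert np.median(draws["gamma0"]) == pytest.approx(1.57, rel=0.05)
        assert np.std(draws["rho_s"]) < 0.05
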