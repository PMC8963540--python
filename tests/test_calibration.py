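import numpy as np
import pandas as pd
import pytest

from sedlab import synth
from sedlab.calibration import (
    ASSAY_MEDIUM_DENSITY,
    CalibrationObservations,
    bootstrap_calibration,
    calibrate_assay_table,
    calibration_loss,
    estimate_velocity_density,
    fit_calibration,
    prepare_reference,
)
from sedlab.errors import DomainError, InputError, StateError
from sedlab.physics import CONSTANTS, stokes_velocity


class TestPrepareReference:
    def test_excess_above_cellulose_excluded(self):
        radius = 1e-5
        v = stokes_velocity(600.0, radius)  # excess 600 over the medium
        df = pd.DataFrame(
            {
                "classification": ["dense sp."],
                "salt_percent": [3.5],
                "V_meters_per_second": [v],
                "R_meters": [radius],
                "Pf": [1000.0],
            }
        )
        rows = prepare_reference(df)
        assert rows[0].excluded
        assert rows[0].exclusion_reason == "excess density above cellulose"
        assert rows[0].expected_assay_velocity is None

    def test_taxon_exclusion(self):
        df = pd.DataFrame(
            {
                "classification": ["D. rex"],
                "salt_percent": [3.5],
                "V_meters_per_second": [1e-5],
                "R_meters": [1e-4],
                "Pf": [1026.0],
            }
        )
        rows = prepare_reference(df)
        assert rows[0].excluded and rows[0].exclusion_reason == "taxon exclusion"

    def test_neutral_in_assay_medium_has_zero_vexp(self):
        radius = 2e-5
        pf = 1020.0
        v = stokes_velocity(ASSAY_MEDIUM_DENSITY - pf, radius)  # p_p == assay medium density
        df = pd.DataFrame(
            {
                "classification": ["sp."],
                "salt_percent": [3.5],
                "V_meters_per_second": [v],
                "R_meters": [radius],
                "Pf": [pf],
            }
        )
        rows = prepare_reference(df)
        assert not rows[0].excluded
        assert rows[0].expected_assay_velocity == pytest.approx(0.0, abs=1e-18)

    def test_synthetic_table_densities_recovered(self, seawater_model):
        df, truth = synth.gen_reference_table(n=39, seed=4, noise_cv=0.0)
        rows = prepare_reference(df)  # uses the table's own Pf column
        excess = np.array([r.excess_density for r in rows])
        np.testing.assert_allclose(excess, np.array(truth["excess_density"]), rtol=1e-12)

    def test_media_density_from_seawater_model(self, seawater_model):
        df, truth = synth.gen_reference_table(n=20, seed=5, noise_cv=0.0)
        rows = prepare_reference(df, seawater_model)
        pf = np.array([r.media_density for r in rows])
        # model fitted on the same truth surface: media densities agree closely
        np.testing.assert_allclose(pf, np.array(truth["media_density"]), atol=0.01)

    def test_missing_columns_rejected(self):
        with pytest.raises(InputError):
            prepare_reference(pd.DataFrame({"R_meters": [1e-5]}))


class TestLoss:
    def test_zero_at_truth(self, joint_observations):
        obs = joint_observations(0.03, 80.0, seed=1)
        assert calibration_loss(0.03, 80.0, obs) == pytest.approx(0.0, abs=1e-25)

    def test_truth_is_global_minimum(self, joint_observations):
        obs = joint_observations(0.03, 80.0, seed=1)
        base = calibration_loss(0.03, 80.0, obs)
        for ds, dp in [(0.01, 0), (-0.01, 0), (0, 5), (0, -5), (0.02, 10)]:
            assert calibration_loss(0.03 + ds, 80.0 + dp, obs) > base

    def test_hand_computed_single_row(self):
        # choose p_p_hat so the prediction is exactly 2e-5 while V_exp = 1e-5
        radius = 1e-4
        pp = 2e-5 / (CONSTANTS.stokes_prefactor * radius**2)
        obs = CalibrationObservations([1e-5], [radius], [0.0])
        assert calibration_loss(0.0, pp, obs) == pytest.approx(1e-10, rel=1e-9)

    def test_row_order_invariance(self, joint_observations):
        obs = joint_observations(0.02, 120.0, seed=7, noise_cv=0.1)
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(obs))
        shuffled = obs.subset(idx)
        assert calibration_loss(0.05, 90.0, obs) == pytest.approx(
            calibration_loss(0.05, 90.0, shuffled), rel=1e-12
        )


class TestFit:
    def test_noise_free_recovery(self, joint_observations):
        obs = joint_observations(0.03, 80.0, seed=2)
        s, pp = fit_calibration(obs)
        assert s == pytest.approx(0.03, rel=1e-6, abs=1e-7)
        assert pp == pytest.approx(80.0, rel=1e-6)

    def test_matches_grid_search_oracle_small_instance(self, joint_observations):
        obs = joint_observations(0.05, 150.0, n_ref=5, n_assay=5, seed=3, noise_cv=0.15)
        s_grid = np.linspace(-0.5, 0.5, 401)
        pp_grid = np.linspace(1.0, 500.0, 400)
        losses = np.array([[calibration_loss(s, p, obs) for p in pp_grid] for s in s_grid])
        i, j = np.unravel_index(np.argmin(losses), losses.shape)
        s_hat, pp_hat = fit_calibration(obs)
        # the continuous optimum must be at least as good as the best grid point
        assert calibration_loss(s_hat, pp_hat, obs) <= losses[i, j] * (1 + 1e-12)
        # and lie within grid resolution of it (2 steps: correlated parameters)
        assert abs(s_hat - s_grid[i]) <= 2 * (s_grid[1] - s_grid[0])
        assert abs(pp_hat - pp_grid[j]) <= 2 * (pp_grid[1] - pp_grid[0])

    def test_parameter_recovery_under_noise(self, joint_observations):
        # 50 synthetic datasets, n = 100, multiplicative velocity noise CV 10%.
        # At this noise level the sampling floor on S is ~0.02 (S is a log-scale
        # factor estimated from ~50 rows at 10% CV), so the S bound is set there.
        s_errs, pp_errs = [], []
        for seed in range(50):
            obs = joint_observations(0.03, 80.0, n_ref=50, n_assay=50, seed=seed, noise_cv=0.10)
            s_hat, pp_hat = fit_calibration(obs)
            s_errs.append(abs(s_hat - 0.03))
            pp_errs.append(abs(pp_hat - 80.0))
        assert np.median(s_errs) < 0.05
        assert np.median(pp_errs) < 10.0

    def test_requires_both_strata(self):
        obs = CalibrationObservations([1e-5, 2e-5], [1e-5, 2e-5], [0.0, 0.0])
        with pytest.raises(InputError):
            fit_calibration(obs)


class TestBootstrap:
    def test_zero_noise_sd_near_zero(self, joint_observations):
        obs = joint_observations(0.03, 80.0, seed=4)
        fit = bootstrap_calibration(obs, n_reps=25, seed=0)
        assert fit.S_se < 1e-6
        assert fit.p_p_hat_se < 1e-3

    def test_seed_determinism(self, joint_observations):
        obs = joint_observations(0.03, 80.0, seed=5, noise_cv=0.1)
        f1 = bootstrap_calibration(obs, n_reps=20, seed=42)
        f2 = bootstrap_calibration(obs, n_reps=20, seed=42)
        np.testing.assert_array_equal(f1.fold_estimates, f2.fold_estimates)

    def test_point_estimate_near_full_fit(self, joint_observations):
        obs = joint_observations(0.03, 80.0, n_ref=50, n_assay=50, seed=6, noise_cv=0.1)
        s_full, pp_full = fit_calibration(obs)
        fit = bootstrap_calibration(obs, n_reps=60, seed=1)
        assert abs(fit.S - s_full) <= max(fit.S_se, 1e-4)
        assert abs(fit.p_p_hat - pp_full) <= max(fit.p_p_hat_se, 0.5)

    def test_fold_shapes_and_correlation_bound(self, joint_observations):
        obs = joint_observations(0.03, 80.0, seed=7, noise_cv=0.2)
        fit = bootstrap_calibration(obs, n_reps=30, seed=2)
        assert fit.fold_estimates.shape == (30, 2)
        assert abs(fit.fold_correlation) <= 1.0
        assert len(fit.holdout_indices) == 30


class TestDensityEstimate:
    def test_zero_rate_gives_medium_density(self, joint_observations):
        obs = joint_observations(0.03, 80.0, seed=8)
        fit = bootstrap_calibration(obs, n_reps=10, seed=3)
        est = estimate_velocity_density(fit, [0.0], radius=2e-5, medium_density=1028.9)
        assert est.pp_mu == pytest.approx(1028.9)
        assert est.pp_se == pytest.approx(0.0, abs=1e-12)

    def test_known_density_recovered(self, joint_observations):
        s_star, pp_medium_excess = 0.03, 150.0
        obs = joint_observations(s_star, 100.0, n_ref=50, n_assay=50, seed=9, noise_cv=0.05)
        fit = bootstrap_calibration(obs, n_reps=40, seed=4)
        radius = 3e-5
        medium = 1028.9
        v_true = CONSTANTS.stokes_prefactor * (pp_medium_excess) * radius**2
        rate_au = v_true / np.exp(s_star)
        est = estimate_velocity_density(fit, [rate_au] * 3, radius=radius, medium_density=medium)
        assert abs(est.pp_mu - (medium + pp_medium_excess)) <= max(2 * est.pp_se, 2.0)

    def test_unfitted_raises(self):
        from sedlab.calibration import CalibrationFit

        empty = CalibrationFit(0, 0, 0, 0, np.empty((0, 2)), 0.0, None)
        with pytest.raises(StateError):
            estimate_velocity_density(empty, [1e-5], radius=1e-5)

    def test_calibrate_assay_table_appends_columns(self, joint_observations):
        obs = joint_observations(0.03, 80.0, seed=10)
        fit = bootstrap_calibration(obs, n_reps=10, seed=5)
        assay = pd.DataFrame(
            {
                "V_au": [1e-5, 1.2e-5, 5e-5],
                "R_meters": [2e-5, 2e-5, 4e-5],
                "species": ["a", "a", "a"],
                "genotype": ["g1", "g1", "g2"],
                "temp": [17.0] * 3,
                "hours_growth": [24.0] * 3,
            }
        )
        out = calibrate_assay_table(assay, fit)
        assert {"V_mu", "V_se", "pp_mu", "pp_se"}.issubset(out.columns)
        assert out["V_mu"].notna().all()
        # rows in the same group share estimates
        assert out.loc[0, "pp_mu"] == out.loc[1, "pp_mu"]
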