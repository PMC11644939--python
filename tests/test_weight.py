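"""Exponential-kernel GPR, linear SVR and density baselines, CV, config stats."""

import numpy as np
import pytest

from trayvol.synth import LinearLaw, generate_weight_dataset
from trayvol.weight import (
    DensityTable,
    ExponentialGPR,
    ExponentialGPRParams,
    VolumeWeightSet,
    config_stats,
    density_weight,
    fit_gpr,
    fit_linear_svr,
    kernel_exponential,
    kfold_cv,
)

P = ExponentialGPRParams(sigma_f2=4.0, length_scale_l=1.5, noise_var=0.01)


class TestKernel:
    def test_zero_distance_returns_signal_variance(self):
        assert kernel_exponential(3.0, 3.0, P) == pytest.approx(4.0)

    def test_symmetry_on_random_pairs(self, rng):
        for _ in range(20):
            a, b = rng.uniform(-10, 10, size=2)
            assert kernel_exponential(a, b, P) == pytest.approx(kernel_exponential(b, a, P))

    def test_distance_two_l_squared_gives_e_minus_one(self):
        # default form: k = sf2 * exp(-r / (2 l^2)), so r = 2 l^2 -> sf2/e
        r = 2 * P.length_scale_l**2
        assert kernel_exponential(0.0, r, P) == pytest.approx(4.0 * np.exp(-1))

    def test_ou_form_decays_at_length_scale(self):
        assert kernel_exponential(0.0, P.length_scale_l, P, kernel_form="ou") == pytest.approx(
            4.0 * np.exp(-1)
        )

    def test_gram_matrices_psd_after_noise_jitter(self, rng):
        for _ in range(10):
            x = rng.uniform(0, 100, size=12)
            K = kernel_exponential(x[:, None], x[None, :], P)
            np.linalg.cholesky(K + P.noise_var * np.eye(12))  # must not raise


class TestGPR:
    def test_two_point_posterior_matches_closed_form(self):
        """Hand-solved 2x2 GP system, no standardization."""
        p = ExponentialGPRParams(sigma_f2=2.0, length_scale_l=1.2, noise_var=0.3)
        x1, x2, xs = 1.0, 3.0, 2.2
        y1, y2 = 5.0, 8.0
        data = VolumeWeightSet(np.array([x1, x2]), np.array([y1, y2]))
        model = ExponentialGPR(standardize=False)
        model.fit(data, init=p, optimize=False)
        mean, var = model.predict([xs])

        k12 = kernel_exponential(x1, x2, p)
        k1s = kernel_exponential(x1, xs, p)
        k2s = kernel_exponential(x2, xs, p)
        a, b = p.sigma_f2 + p.noise_var, k12
        det = a * a - b * b
        inv = np.array([[a, -b], [-b, a]]) / det  # explicit 2x2 inverse
        ks = np.array([k1s, k2s])
        ybar = (y1 + y2) / 2  # GP prior mean = training mean
        mu = ks @ inv @ np.array([y1 - ybar, y2 - ybar]) + ybar
        v = p.sigma_f2 + p.noise_var - ks @ inv @ ks
        assert mean[0] == pytest.approx(mu, abs=1e-10)
        assert var[0] == pytest.approx(v, abs=1e-10)

    def test_optimize_off_keeps_init_params(self):
        data = VolumeWeightSet(np.array([1e5, 2e5, 3e5]), np.array([100.0, 180.0, 290.0]))
        init = ExponentialGPRParams(100.0, 0.7, 1.0)
        model = fit_gpr(data, init=init, optimize=False)
        assert model.params_ == init

    def test_duplicate_inputs_fit_through_noise_term(self):
        data = VolumeWeightSet(
            np.array([2e5, 2e5, 3e5, 3.5e5]), np.array([200.0, 210.0, 300.0, 330.0])
        )
        model = fit_gpr(data, seed=0)  # must not raise despite duplicate volumes
        assert model.params_.noise_var > 0

    def test_posterior_interpolates_as_noise_vanishes(self):
        x = np.array([1e5, 2e5, 3e5])
        y = np.array([100.0, 210.0, 290.0])
        model = fit_gpr(
            VolumeWeightSet(x, y),
            init=ExponentialGPRParams(5000.0, 1.0, 1e-8),
            optimize=False,
        )
        mean, var = model.predict(x)
        assert np.allclose(mean, y, atol=1e-3)
        assert np.all(var < 5000.0)

    def test_far_from_data_reverts_to_prior(self):
        x = np.array([1e5, 1.1e5, 1.2e5])
        y = np.array([100.0, 105.0, 110.0])
        model = ExponentialGPR(standardize=False)
        model.fit(
            VolumeWeightSet(x, y),
            init=ExponentialGPRParams(50.0, 2.0, 1.0),
            optimize=False,
        )
        mean, var = model.predict([1e9])
        assert mean[0] == pytest.approx(y.mean(), abs=1e-6)  # prior mean = centred 0
        assert var[0] == pytest.approx(50.0 + 1.0, rel=1e-6)  # sf2 + noise

    def test_training_point_prediction_shrinks(self):
        data = VolumeWeightSet(np.array([1e5, 2e5, 3e5]), np.array([100.0, 220.0, 290.0]))
        model = fit_gpr(data, init=ExponentialGPRParams(5000.0, 1.0, 50.0), optimize=False)
        mean, var = model.predict([2e5])
        lo, hi = sorted([float(data.weights_g.mean()), 220.0])
        assert lo <= mean[0] <= hi
        assert var[0] < 5000.0

    def test_hyperparameter_recovery_from_gp_draw(self, rng):
        """Simulate from a known OU GP; the fit must find comparable structure."""
        n = 200
        true = ExponentialGPRParams(sigma_f2=1.0, length_scale_l=0.05, noise_var=0.0625)
        x = np.sort(rng.uniform(0, 1, n))
        K = kernel_exponential(x[:, None], x[None, :], true, "ou")
        f = np.linalg.cholesky(K + 1e-10 * np.eye(n)) @ rng.normal(size=n)
        y = f + rng.normal(0, np.sqrt(true.noise_var), n)
        data = VolumeWeightSet(x * 1e3 + 50, y + 20)
        model = ExponentialGPR(kernel_form="ou").fit(data, seed=0, n_restarts=6)
        l_natural = model.params_.length_scale_l * model._x_std / 1e3
        assert 0.5 * true.length_scale_l <= l_natural <= 2.0 * true.length_scale_l
        # the optimized LML cannot fall more than 1 nat below the truth's
        truth_std = ExponentialGPRParams(
            true.sigma_f2, true.length_scale_l * 1e3 / model._x_std, true.noise_var
        )
        assert model.log_marginal_likelihood_ >= model.log_marginal_likelihood(truth_std) - 1.0

    def test_agrees_with_reference_gp_implementation(self):
        """Cross-check posterior mean against sklearn's Matern(nu=0.5) GP."""
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

        rng = np.random.default_rng(7)
        x = rng.uniform(0, 10, 30)
        y = np.sin(x) * 3 + 10 + rng.normal(0, 0.1, 30)
        p = ExponentialGPRParams(sigma_f2=2.0, length_scale_l=1.5, noise_var=0.01)
        ours = ExponentialGPR(kernel_form="ou", standardize=False)
        ours.fit(VolumeWeightSet(x + 1, y), init=p, optimize=False)

        ref = GaussianProcessRegressor(
            kernel=ConstantKernel(p.sigma_f2, "fixed")
            * Matern(length_scale=p.length_scale_l, nu=0.5, length_scale_bounds="fixed")
            + WhiteKernel(p.noise_var, "fixed"),
            optimizer=None,
            normalize_y=False,
        )
        ref.fit((x + 1)[:, None], y - y.mean())
        xs = np.linspace(1, 11, 17)
        ours_mean, _ = ours.predict(xs)
        ref_mean = ref.predict(xs[:, None]) + y.mean()
        assert np.allclose(ours_mean, ref_mean, atol=1e-8)

    def test_json_round_trip_preserves_predictions(self, tmp_path):
        data = VolumeWeightSet(np.array([1e5, 2e5, 3e5, 4e5]), np.array([100.0, 210.0, 290.0, 360.0]))
        model = fit_gpr(data, seed=0)
        model.to_json(tmp_path / "m.json")
        back = ExponentialGPR.from_json(tmp_path / "m.json")
        xs = [1.5e5, 2.5e5]
        assert np.allclose(model.predict(xs)[0], back.predict(xs)[0])


class TestLinearSVR:
    def test_noiseless_line_recovered(self):
        v = np.linspace(1e5, 4e5, 20)
        data = VolumeWeightSet(v, 0.001 * v)
        model = fit_linear_svr(data, epsilon=0.0, C=10.0)
        assert model.slope_ == pytest.approx(0.001, abs=1e-6)
        assert model.intercept_ == pytest.approx(0.0, abs=1e-2)

    def test_point_inside_epsilon_tube_does_not_move_fit(self):
        v = np.linspace(1e5, 4e5, 12)
        data = VolumeWeightSet(v, 0.001 * v)
        base = fit_linear_svr(data, epsilon=5.0, C=10.0)
        v2 = np.append(v, 2.5e5)
        w2 = np.append(0.001 * v, 0.001 * 2.5e5 + 1.0)  # inside the 5 g tube
        shifted = fit_linear_svr(VolumeWeightSet(v2, w2), epsilon=5.0, C=10.0)
        assert shifted.slope_ == pytest.approx(base.slope_, rel=1e-4)
        assert shifted.intercept_ == pytest.approx(base.intercept_, abs=0.05)

    def test_cv_rmse_tracks_noise_level(self):
        data = generate_weight_dataset(120, LinearLaw(), noise_sigma_g=8.0, seed=3)
        rep = kfold_cv(data, "linear_svr", k=5, seed=3)
        assert rep.rmse_g == pytest.approx(8.0, rel=0.25)

    def test_degenerate_volumes_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_linear_svr(VolumeWeightSet(np.full(5, 2e5), np.linspace(100, 200, 5)))


class TestDensity:
    TABLE = DensityTable({"rice": 0.0008, "chicken": 0.00105})

    def test_weight_is_density_times_volume(self):
        assert density_weight(250_000.0, "rice", self.TABLE) == pytest.approx(200.0)

    def test_zero_volume_zero_weight(self):
        assert density_weight(0.0, "rice", self.TABLE) == 0.0

    def test_linearity(self):
        assert density_weight(2 * 123_456.0, "chicken", self.TABLE) == pytest.approx(
            2 * density_weight(123_456.0, "chicken", self.TABLE)
        )

    def test_unknown_class_lists_known(self):
        with pytest.raises(ValueError, match="chicken"):
            density_weight(1.0, "pasta", self.TABLE)


class PerfectModel:
    """Oracle predictor that knows the generating law exactly."""

    def __init__(self, law):
        self.law = law

    def fit(self, data):
        return self

    def predict(self, volumes):
        return np.asarray(self.law(volumes))


class MeanModel:
    def fit(self, data):
        self.mean = float(data.weights_g.mean())
        return self

    def predict(self, volumes):
        return np.full(len(volumes), self.mean)


class TestKFoldCV:
    def test_perfect_model_has_zero_error(self):
        law = LinearLaw()
        data = generate_weight_dataset(30, law, seed=1)
        rep = kfold_cv(data, lambda: PerfectModel(law), k=5, seed=1)
        assert rep.rmse_g == 0.0 and rep.mape_pct == 0.0

    def test_constant_predictor_matches_hand_computation(self):
        vols = np.array([1e5, 1.5e5, 2e5, 2.5e5, 3e5, 3.5e5])
        wts = np.array([100.0, 150.0, 200.0, 250.0, 300.0, 350.0])
        data = VolumeWeightSet(vols, wts)
        rep = kfold_cv(data, MeanModel, k=3, seed=0)
        # recompute by hand from the recorded fold assignment
        errs = []
        for fold in range(3):
            te = np.array(rep.fold_assignment) == fold
            errs.extend(wts[~te].mean() - wts[te])
        assert rep.rmse_g == pytest.approx(np.sqrt(np.mean(np.square(errs))))

    def test_folds_partition_all_records_evenly(self):
        data = generate_weight_dataset(23, LinearLaw(), seed=2)
        rep = kfold_cv(data, MeanModel, k=5, seed=2)
        counts = np.bincount(rep.fold_assignment, minlength=5)
        assert counts.sum() == 23 and counts.max() - counts.min() <= 1

    def test_too_few_records_rejected(self):
        data = VolumeWeightSet(np.array([1e5, 2e5, 3e5]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="at least"):
            kfold_cv(data, MeanModel, k=5)


class TestConfigStats:
    def test_printed_volume_rows_reproduce_known_stds(self):
        groups = {
            "Comp.": [254145, 239256, 277954, 286303],
            "1/8 Acc.": [295410, 310579, 291054, 304708],
        }
        stats = {s.config_id: s.rounded() for s in config_stats(groups)}
        assert stats["Comp."]["std_mm3"] == 21_609
        assert stats["1/8 Acc."]["std_mm3"] == 8_840

    def test_identical_values_have_zero_std(self):
        (s,) = config_stats({"c": [5.0, 5.0, 5.0]})
        assert s.std_mm3 == 0.0

    def test_single_record_reports_missing_std(self):
        (s,) = config_stats({"c": [5.0]})
        assert s.std_mm3 is None and s.n == 1
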