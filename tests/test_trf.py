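"""Ridge TRF estimation, cross-validation, scoring, cross-encoding."""

import numpy as np
import pytest

from modtrf import (
    cross_encode,
    fit_trf,
    lag_grid,
    lagged_design,
    matched_band_summary,
    modulation_band_encode,
    predict_score,
    train_with_cv,
)


class TestLaggedDesign:
    def test_zero_lag_is_identity(self):
        x = np.arange(5.0)
        d = lagged_design(x, np.array([0]))
        assert np.allclose(d[:, 0], 1.0)
        assert np.allclose(d[:, 1], x)

    def test_impulse_gives_shifted_identity(self):
        x = np.zeros(6)
        x[0] = 1.0
        d = lagged_design(x, np.arange(4), intercept=False)
        assert np.allclose(d, np.eye(6)[:, :4])

    def test_design_times_kernel_equals_convolution(self):
        # convolution oracle
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        k = rng.standard_normal(12)
        d = lagged_design(x, np.arange(12), intercept=False)
        assert np.allclose(d @ k, np.convolve(x, k)[:200], atol=1e-10)

    def test_lag_grid_covers_window(self):
        lags = lag_grid(0.0, 500.0, 128.0)
        assert lags[0] == 0
        assert lags[-1] == 64


class TestFitTRF:
    def test_scalar_ols_exact(self):
        x = np.array([[1.0], [2.0], [3.0]])
        y = np.array([2.0, 4.0, 6.0])
        model = fit_trf(x, y, lam=0.0, intercept=False)
        assert model.kernel[0] == pytest.approx(2.0, abs=1e-12)

    def test_scalar_ridge_closed_form(self):
        # (sum x^2 + lam)^-1 sum xy = 28/28 = 1
        x = np.array([[1.0], [2.0], [3.0]])
        y = np.array([2.0, 4.0, 6.0])
        model = fit_trf(x, y, lam=14.0, intercept=False)
        assert model.kernel[0] == pytest.approx(1.0, abs=1e-12)

    def test_shrinkage_limit(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((100, 5))
        y = rng.standard_normal(100)
        ols = fit_trf(x, y, lam=0.0, intercept=False)
        huge = fit_trf(x, y, lam=1e9, intercept=False)
        assert np.linalg.norm(huge.kernel) < 1e-6 * np.linalg.norm(ols.kernel)

    def test_matches_normal_equations_oracle(self):
        # brute-force oracle on random small problems, intercept unpenalized
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = rng.integers(30, 500)
            p = rng.integers(2, 20)
            x = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
            y = rng.standard_normal(n)
            lam = 10.0 ** rng.uniform(-2, 4)
            m = np.eye(p + 1)
            m[0, 0] = 0.0
            expected = np.linalg.solve(x.T @ x + lam * m, x.T @ y)
            model = fit_trf(x, y, lam=lam)
            got = np.concatenate([[model.intercept], model.kernel])
            assert np.allclose(got, expected, rtol=1e-8)

    def test_kernel_norm_nonincreasing_in_lambda(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((200, 10))
        y = rng.standard_normal(200)
        norms = [np.linalg.norm(fit_trf(x, y, lam=l, intercept=False).kernel)
                 for l in np.logspace(-2, 6, 9)]
        assert np.all(np.diff(norms) <= 1e-12)

    def test_singular_unregularized_fit_raises(self):
        x = np.ones((10, 3))  # rank 1
        y = np.ones(10)
        with pytest.raises(np.linalg.LinAlgError):
            fit_trf(x, y, lam=0.0, intercept=False)


class TestPredictScore:
    def test_exact_generative_model_hits_clipped_max(self):
        rng = np.random.default_rng(4)
        env = rng.standard_normal(500)
        lags = np.arange(8)
        k = rng.standard_normal(8)
        from modtrf import standardize_trial

        e_std, _ = standardize_trial(env, env)
        d = lagged_design(e_std, lags, intercept=False)
        resp = d @ k
        model = fit_trf(lagged_design(e_std, lags), resp, lam=0.0, lags=lags)
        with pytest.warns(UserWarning):
            res = predict_score(model, env, resp)
        assert res.z == pytest.approx(np.arctanh(1 - 1e-12))

    def test_independent_noise_scores_near_zero(self):
        rng = np.random.default_rng(5)
        env = rng.standard_normal(10_000)
        resp = rng.standard_normal(10_000)
        lags = np.arange(5)
        model = fit_trf(lagged_design(np.ones(3), lags), np.zeros(3), lam=1.0,
                        lags=lags)
        # fixed small random kernel, scored on independent noise
        model = fit_trf(lagged_design(env[:100], lags), resp[:100], lam=10.0,
                        lags=lags)
        res = predict_score(model, env[100:], resp[100:])
        assert abs(res.z) < 0.03

    def test_fisher_z_closed_form(self):
        from modtrf import fisher_z

        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_constant_series_raises(self):
        lags = np.arange(3)
        model = fit_trf(lagged_design(np.arange(50.0), lags),
                        np.arange(50.0), lam=1.0, lags=lags)
        with pytest.raises(ValueError):
            predict_score(model, np.ones(50), np.arange(50.0))


def _synthetic_trials(rng, kernel, n_trials=12, n_samples=300, noise=0.0):
    lags = np.arange(len(kernel))
    trials = []
    for _ in range(n_trials):
        env = rng.standard_normal(n_samples)
        d = lagged_design((env - env.mean()) / env.std(), lags, intercept=False)
        resp = d @ kernel + noise * rng.standard_normal(n_samples)
        trials.append((env, resp))
    return trials


class TestTrainWithCV:
    def test_noiseless_trials_pick_small_lambda_and_high_score(self):
        rng = np.random.default_rng(6)
        kernel = np.array([0.0, 1.0, 0.5, -0.3, 0.1])
        trials = _synthetic_trials(rng, kernel, noise=1e-6)
        grid = tuple(np.logspace(-2, 4, 7))
        model, res = train_with_cv(trials, lambda_grid=grid,
                                   lags=np.arange(5))
        assert res.lambda_used <= grid[len(grid) // 2]
        assert res.z > 2.0
        assert np.corrcoef(model.kernel, kernel)[0, 1] > 0.999

    def test_pure_noise_scores_near_zero(self):
        rng = np.random.default_rng(7)
        trials = [(rng.standard_normal(300), rng.standard_normal(300))
                  for _ in range(50)]
        _, res = train_with_cv(trials, lambda_grid=(1.0, 100.0),
                               lags=np.arange(5))
        assert abs(res.z) < 0.05

    def test_single_lambda_grid_returns_it(self):
        rng = np.random.default_rng(8)
        trials = _synthetic_trials(rng, np.array([1.0, 0.5]), n_trials=3)
        _, res = train_with_cv(trials, lambda_grid=(3.14,), lags=np.arange(2))
        assert res.lambda_used == 3.14

    def test_kfold10_runs_on_segments(self):
        rng = np.random.default_rng(9)
        trials = _synthetic_trials(rng, np.array([1.0, -0.5]), n_trials=10)
        model, res = train_with_cv(trials, lambda_grid=(0.1, 10.0),
                                   scheme="kfold10", lags=np.arange(2))
        assert res.n == 10
        assert np.isfinite(res.z)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            train_with_cv([(np.ones(10), np.ones(10))] * 2, lambda_grid=())


class TestCrossEncode:
    def test_shared_kernel_generalizes(self):
        rng = np.random.default_rng(10)
        kernel = np.array([1.0, 0.6, -0.4, 0.2])
        sets = {f"t{i}": _synthetic_trials(rng, kernel, noise=0.3)
                for i in range(3)}
        models, own = {}, {}
        for label, trials in sets.items():
            m, r = train_with_cv(trials, lambda_grid=(1.0, 100.0),
                                 lags=np.arange(4), train_label=label)
            models[label], own[label] = m, r.z
        mat = cross_encode(models, sets, own_performance=own)
        v = mat.values.to_numpy(dtype=float)
        diag = np.diag(v)
        off = (v.sum(axis=1) - diag) / (v.shape[1] - 1)
        assert np.all(np.abs(diag - off) < 0.05)

    def test_specific_kernels_show_diagonal_advantage(self):
        rng = np.random.default_rng(11)
        kernels = {"a": np.array([1.0, 0.0, 0.0, 0.0]),
                   "b": np.array([0.0, 0.0, 1.0, -1.0]),
                   "c": np.array([-1.0, 1.0, -1.0, 1.0])}
        sets = {l: _synthetic_trials(rng, k, noise=0.5)
                for l, k in kernels.items()}
        models, own = {}, {}
        for label, trials in sets.items():
            m, r = train_with_cv(trials, lambda_grid=(1.0, 100.0),
                                 lags=np.arange(4), train_label=label)
            models[label], own[label] = m, r.z
        mat = cross_encode(models, sets, own_performance=own)
        v = mat.values.to_numpy(dtype=float)
        diag = np.diag(v)
        off = (v.sum(axis=1) - diag) / (v.shape[1] - 1)
        assert np.all(diag > off)

    def test_matrix_shape_and_missing_set_rejected(self):
        rng = np.random.default_rng(12)
        sets = {f"t{i}": _synthetic_trials(rng, np.array([1.0, 0.5]))
                for i in range(2)}
        models = {}
        for label, trials in sets.items():
            models[label], _ = train_with_cv(trials, lambda_grid=(1.0,),
                                             lags=np.arange(2),
                                             train_label=label)
        mat = cross_encode(models, sets)
        assert mat.values.shape == (2, 2)
        with pytest.raises(ValueError):
            cross_encode({}, sets)


class TestModulationBandEncode:
    def test_band_specific_drive_peaks_in_matching_cell(self):
        # response driven only by the 4-6 Hz envelope component
        from modtrf import bandpass_filter

        rng = np.random.default_rng(13)
        fs = 64.0
        n = 640
        kernel = np.exp(-0.5 * ((np.arange(8) - 3) / 1.5) ** 2)
        trials = []
        for _ in range(8):
            env = rng.standard_normal(n)
            drive = bandpass_filter(env, 4.0, 6.0, fs)
            d = lagged_design(drive, np.arange(8), intercept=False)
            resp = d @ kernel + 0.05 * rng.standard_normal(n)
            trials.append((env, resp))
        grid = modulation_band_encode(
            trials, fs=fs,
            neural_bands={"theta": (4.0, 7.0)},
            mod_bands=[(1.0, 3.0), (3.0, 5.0), (5.0, 7.0), (9.0, 11.0)],
            lambda_grid=(0.1, 10.0), lags=np.arange(8),
        )
        best = grid["theta"].astype(float).idxmax()
        assert best in (4.0, 6.0)  # the two bands overlapping 4-6 Hz

    def test_grid_dimensions_default(self):
        from modtrf.trf import default_modulation_bands

        bands = default_modulation_bands()
        assert len(bands) == 22
        assert bands[0] == (1.0, 3.0)
        assert bands[-1] == (43.0, 45.0)

    def test_degenerate_band_left_missing(self):
        rng = np.random.default_rng(14)
        fs = 64.0
        t = np.arange(640) / fs
        env = np.sin(2 * np.pi * 5.0 * t)  # no content near 20 Hz
        trials = [(env, rng.standard_normal(640)) for _ in range(3)]
        grid = modulation_band_encode(
            trials, fs=fs, neural_bands={"theta": (4.0, 7.0)},
            mod_bands=[(19.0, 21.0)], lambda_grid=(1.0,), lags=np.arange(4),
        )
        assert grid.isna().all().all()

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            modulation_band_encode([(np.ones(64), np.ones(64))], fs=64.0,
                                   mod_bands=[(30.0, 40.0)])

    def test_matched_band_summary_averages_overlapping_rows(self):
        import pandas as pd

        grid = pd.DataFrame({"theta": [0.1, 0.3, 0.5]},
                            index=pd.Index([2.0, 4.0, 6.0], name="mod_band_hz"))
        out = matched_band_summary(grid, {"theta": (4.0, 7.0)})
        assert out["theta"] == pytest.approx(np.mean([0.3, 0.5]))
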