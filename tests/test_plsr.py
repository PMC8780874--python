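import numpy as np
import pytest

from aquanir import synth
from aquanir.errors import DegenerateDataError, DimensionError
from aquanir.io import MixtureDesign
from aquanir.plsr import (
    cross_validate,
    fit_plsr,
    predict,
    r_squared,
    rmse,
    scan_triplet_scheme,
)
from aquanir.preprocess import PreprocessSpec, apply_chain

from conftest import make_block, random_block


class TestMetrics:
    def test_hand_computed_r_squared(self):
        assert r_squared([0.0, 10.0], [1.0, 9.0]) == pytest.approx(0.96, abs=1e-12)

    def test_r_squared_extremes(self):
        y = np.array([1.0, 2.0, 4.0])
        assert r_squared(y, y) == 1.0
        assert r_squared(y, np.full(3, y.mean())) == 0.0

    def test_hand_computed_rmse(self):
        assert rmse([0.0, 10.0], [1.0, 9.0]) == pytest.approx(1.0, abs=1e-12)
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_rmse_scale_equivariant(self, rng):
        y, yhat = rng.random(20), rng.random(20)
        assert rmse(3.5 * y, 3.5 * yhat) == pytest.approx(3.5 * rmse(y, yhat), rel=1e-12)

    def test_constant_y_rejected(self):
        with pytest.raises(DegenerateDataError):
            r_squared([2.0, 2.0], [1.0, 3.0])


class TestFit:
    def test_single_component_fits_rank_one_response(self, rng):
        direction = rng.random(30)
        t = rng.standard_normal(12)
        block = make_block(np.outer(t, direction))
        y = 2.0 + 3.0 * t
        model = fit_plsr(block, y, 1)
        assert model.metrics["RMSEC"] < 1e-8

    def test_first_weight_proportional_to_cross_covariance(self, rng):
        block = random_block(rng, 15, 10)
        y = rng.random(15) * 10
        model = fit_plsr(block, y, 3)
        Xc = block.absorbance - block.absorbance.mean(axis=0)
        yc = y - y.mean()
        w_expected = Xc.T @ yc
        w_expected /= np.linalg.norm(w_expected)
        np.testing.assert_allclose(model.weights[:, 0], w_expected, atol=1e-10)

    def test_full_rank_matches_ordinary_least_squares(self, rng):
        """With as many latent variables as the rank of X, PLS spans the full
        predictor space and reproduces the OLS fit."""
        block = random_block(rng, 20, 6)
        y = rng.random(20) * 30
        model = fit_plsr(block, y, 6)
        Xc = block.absorbance - block.absorbance.mean(axis=0)
        beta = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        ols_pred = y.mean() + Xc @ beta
        np.testing.assert_allclose(predict(model, block), ols_pred, atol=1e-8)

    def test_matches_scikit_learn_predictions(self, rng):
        PLSRegression = pytest.importorskip("sklearn.cross_decomposition").PLSRegression
        block = random_block(rng, 25, 40)
        y = rng.random(25) * 100
        model = fit_plsr(block, y, 5)
        ref = PLSRegression(n_components=5, scale=False).fit(block.absorbance, y)
        np.testing.assert_allclose(
            predict(model, block), ref.predict(block.absorbance).ravel(), atol=1e-6
        )

    def test_training_scores_mutually_orthogonal(self, rng):
        block = random_block(rng, 18, 12)
        y = rng.random(18) * 5
        model = fit_plsr(block, y, 5)
        Xc = block.absorbance - model.x_mean
        T = np.zeros((18, 5))
        for k in range(5):
            T[:, k] = Xc @ model.weights[:, k]
            Xc = Xc - np.outer(T[:, k], model.x_loadings[:, k])
        G = T.T @ T
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)

    def test_constant_response_rejected(self, rng):
        with pytest.raises(DegenerateDataError):
            fit_plsr(random_block(rng, 8, 5), np.full(8, 7.0), 2)


class TestPredict:
    def test_mean_spectrum_predicts_mean_response(self, rng):
        block = random_block(rng, 10, 8)
        y = rng.random(10) * 50
        model = fit_plsr(block, y, 3)
        mean_block = make_block(model.x_mean[None, :])
        assert predict(model, mean_block)[0] == pytest.approx(model.y_mean, abs=1e-10)

    def test_invariant_to_directions_orthogonal_to_coefficients(self, rng):
        block = random_block(rng, 10, 8)
        y = rng.random(10) * 50
        model = fit_plsr(block, y, 3)
        v = rng.standard_normal(8)
        v -= (v @ model.coef) / (model.coef @ model.coef) * model.coef
        shifted = make_block(block.absorbance + v)
        np.testing.assert_allclose(predict(model, shifted), predict(model, block), atol=1e-8)

    def test_regression_vector_equals_latent_path(self, rng):
        block = random_block(rng, 14, 20)
        y = rng.random(14) * 10
        model = fit_plsr(block, y, 4)
        np.testing.assert_allclose(
            predict(model, block), model.predict_latent(block.absorbance), atol=1e-10
        )

    def test_grid_mismatch_rejected(self, rng):
        model = fit_plsr(random_block(rng, 8, 6), rng.random(8), 2)
        with pytest.raises(DimensionError):
            predict(model, random_block(rng, 2, 6, start_nm=888.0))


class TestCrossValidation:
    def test_noiseless_affine_data_gives_perfect_cv(self):
        ara, rob = synth.default_endmembers()
        design = MixtureDesign(levels=(5, 20, 35), n_replicates=3, n_refills=1, n_scans=3)
        block = synth.generate_mixture_dataset(ara, rob, design, synth.NoiseModel(), form="ground")
        y = block.meta["robusta_fraction"].to_numpy(dtype=float)
        cv = cross_validate(block, y, scan_triplet_scheme(), 3)
        row = cv.row(1)
        assert row["R2CV"] == pytest.approx(1.0, abs=1e-10)
        assert row["RMSECV"] < 1e-8

    def test_leave_scan_triplet_out_builds_one_fold_per_replicate(self):
        ara, rob = synth.default_endmembers()
        design = MixtureDesign(levels=(5, 35), n_replicates=3, n_refills=1, n_scans=3)
        block = synth.generate_mixture_dataset(ara, rob, design, synth.noise_preset("low", 1), form="ground")
        from aquanir._cv import build_folds

        folds = build_folds(block.meta, scan_triplet_scheme())
        assert len(folds) == 4 * 3  # sample types x replicates
        assert all(len(f) == 3 for f in folds)

    def test_selected_component_count_minimizes_rmsecv(self):
        ara, rob = synth.default_endmembers()
        design = MixtureDesign(levels=(2, 5, 20, 35), n_replicates=3, n_refills=1, n_scans=3)
        block = synth.generate_mixture_dataset(ara, rob, design, synth.noise_preset("realistic", 9), form="ground")
        y = block.meta["robusta_fraction"].to_numpy(dtype=float)
        cv = cross_validate(block, y, scan_triplet_scheme(), 5)
        assert cv.row(cv.selected)["RMSECV"] <= cv.row(1)["RMSECV"]
        assert cv.row(cv.selected)["RMSECV"] == cv.table["RMSECV"].min()


class TestSyntheticRecovery:
    def _ground_cv(self, seed, preset="low", max_k=5):
        ara, rob = synth.default_endmembers()
        design = MixtureDesign(levels=(1, 2, 3, 5, 10, 20, 35), n_replicates=3, n_refills=1, n_scans=3)
        block = synth.generate_mixture_dataset(ara, rob, design, synth.noise_preset(preset, seed), form="ground")
        pre = apply_chain(block, PreprocessSpec.parse("truncate:1300,1600|savgol:19,2,1"))
        y = pre.meta["robusta_fraction"].to_numpy(dtype=float)
        return pre, y, cross_validate(pre, y, scan_triplet_scheme(), max_k)

    def test_cv_predictions_unbiased_per_level(self):
        """Mean CV prediction error at every fraction level is statistically
        indistinguishable from zero over 20 simulation seeds.  Nine levels
        are tested simultaneously, so the two-sided 5% bound is
        Bonferroni-adjusted (z = 2.77 standard errors per level)."""
        errors = {}
        for seed in range(20):
            pre, y, cv = self._ground_cv(seed)
            err = cv.predictions - y
            for level in np.unique(y):
                errors.setdefault(level, []).append(err[y == level].mean())
        z_bonf = 2.77  # two-sided 5% across 9 levels
        for level, errs in errors.items():
            errs = np.asarray(errs)
            se = errs.std(ddof=1) / np.sqrt(len(errs))
            assert abs(errs.mean()) < z_bonf * se + 1e-9, f"bias at level {level}"

    def test_rmsecv_monotone_in_noise_level(self):
        """RMSECV does not decrease as the noise preset strengthens."""
        vals = []
        for preset in ("none", "low", "realistic"):
            rmsecvs = [self._ground_cv(seed, preset)[2].table["RMSECV"].min() for seed in range(3)]
            vals.append(np.mean(rmsecvs))
        assert vals[0] <= vals[1] + 1e-9 <= vals[2] + 1e-9

    def test_regression_vector_peaks_at_endmember_difference_peaks(self):
        """Local extrema of the regression-vector magnitude co-locate (within
        one grid step) with those of the processed endmember-difference
        spectrum — the bands that actually carry the fraction signal."""
        from scipy.signal import find_peaks

        from aquanir.io import default_grid

        ara, rob = synth.default_endmembers()
        design = MixtureDesign(levels=(1, 2, 3, 5, 10, 20, 35), n_replicates=3, n_refills=1, n_scans=3)
        block = synth.generate_mixture_dataset(ara, rob, design, synth.noise_preset("low", 0), form="ground")
        chain = PreprocessSpec.parse("truncate:1300,1600|savgol:19,2,0")
        pre = apply_chain(block, chain)
        y = pre.meta["robusta_fraction"].to_numpy(dtype=float)
        model = fit_plsr(pre, y, 2)

        grid = default_grid()
        diff = synth.endmember_spectrum(rob, grid) - synth.endmember_spectrum(ara, grid)
        dblock = make_block(np.vstack([diff, diff]), start_nm=grid.start_nm)
        dproc = apply_chain(dblock, chain).absorbance[0]

        lam = pre.grid.values
        dpeaks, _ = find_peaks(np.abs(dproc), prominence=0.2 * np.abs(dproc).max())
        cpeaks, _ = find_peaks(np.abs(model.coef), prominence=0.05 * np.abs(model.coef).max())
        assert len(dpeaks) >= 3
        for j in dpeaks:
            nearest = np.min(np.abs(lam[cpeaks] - lam[j]))
            assert nearest <= pre.grid.step_nm + 1e-9
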