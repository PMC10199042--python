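"""Synthetic landscape generator: determinism, known-truth recovery, design geometry."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import curve_fit

from socmap.plots import extract_at_plots
from socmap.raster import RasterError, align_stack
from socmap.synth import (
    NoiseParams,
    gaussian_field,
    generate_categorical_map,
    generate_dem,
    make_landscape,
    sample_plots,
    simulate_soc_truth,
)
from socmap.variogram import empirical_variogram

from conftest import make_raster


def sampled_variogram(values, n=2500, cell=30.0, max_d=1800.0, bins=30, seed=1):
    rng = np.random.default_rng(seed)
    nr, nc = values.shape
    rows = rng.integers(0, nr, n)
    cols = rng.integers(0, nc, n)
    locs = np.column_stack([cols * cell, rows * cell])
    return empirical_variogram(locs, values[rows, cols], max_d, bins)


class TestGenerateDEM:
    def test_seeded_determinism(self):
        a = generate_dem(64, 64, seed=5)
        b = generate_dem(64, 64, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_zero_relief_is_constant(self):
        dem = generate_dem(64, 64, relief_amplitude=0.0, base_elevation=300.0, seed=0)
        assert np.allclose(dem.values, 300.0)

    def test_relief_span_is_exact(self):
        dem = generate_dem(64, 64, relief_amplitude=2500.0, base_elevation=100.0, seed=1)
        assert dem.values.min() == pytest.approx(100.0)
        assert dem.values.max() == pytest.approx(2600.0)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_larger_spectral_exponent_longer_correlation(self, seed):
        rough = generate_dem(128, 128, spectral_exponent=2.2, seed=seed)
        smooth = generate_dem(128, 128, spectral_exponent=3.8, seed=seed)

        def corr_len(dem):
            res = sampled_variogram(dem.values, n=1500, max_d=3000.0)
            half = 0.5 * np.nanmax(res.gamma)
            return res.bin_centers[np.nonzero(res.gamma >= half)[0][0]]

        assert corr_len(smooth) > corr_len(rough)

    def test_small_grid_rejected(self):
        with pytest.raises(RasterError, match="64"):
            generate_dem(32, 32)


class TestCategoricalMap:
    def test_two_classes_split_at_median(self):
        dem = generate_dem(64, 64, seed=2)
        cats = generate_categorical_map(dem, 2, band_noise=0.0).values
        median = np.median(dem.values)
        assert (cats[dem.values <= median] == 1).all()
        assert (cats[dem.values > median] == 2).all()

    def test_single_class_rejected(self):
        dem = generate_dem(64, 64, seed=0)
        with pytest.raises(RasterError, match="2"):
            generate_categorical_map(dem, 1)

    @pytest.mark.parametrize("k", [3, 8, 21])
    def test_all_classes_present(self, k):
        dem = generate_dem(64, 64, seed=4)
        cats = generate_categorical_map(dem, k, band_noise=100.0, seed=1).values
        assert set(np.unique(cats)) == set(range(1, k + 1))


class TestSOCTruth:
    def _unit_stack(self):
        dem = generate_dem(64, 64, seed=3)
        cats = generate_categorical_map(dem, 3, band_noise=0.0)
        return align_stack(
            {"elev": dem, "soil": cats},
            kinds={"elev": "continuous", "soil": "categorical"},
        )

    def test_all_zero_model_gives_constant_intercept(self):
        stack = self._unit_stack()
        truth = simulate_soc_truth(
            stack, {"elev": 0.0}, {"soil": {1: 0.0, 2: 0.0, 3: 0.0}},
            NoiseParams(), intercept=75.0,
        )
        assert np.allclose(truth.soc_mean_map.values, 75.0)
        assert np.allclose(truth.soc_realized_map.values, 75.0)

    def test_zero_noise_realized_equals_mean(self):
        stack = self._unit_stack()
        truth = simulate_soc_truth(
            stack, {"elev": 0.01}, {"soil": {1: -5.0, 2: 0.0, 3: 5.0}},
            NoiseParams(), intercept=40.0,
        )
        np.testing.assert_array_equal(
            truth.soc_realized_map.values, truth.soc_mean_map.values
        )

    def test_missing_coefficient_rejected(self):
        stack = self._unit_stack()
        with pytest.raises(RasterError, match="coefficient"):
            simulate_soc_truth(stack, {}, {"soil": {1: 0, 2: 0, 3: 0}}, NoiseParams())

    def test_nugget_only_noise_has_flat_variogram(self):
        stack = self._unit_stack()
        nugget = 25.0
        truth = simulate_soc_truth(
            stack, {"elev": 0.0}, {"soil": {1: 0.0, 2: 0.0, 3: 0.0}},
            NoiseParams(partial_sill=0.0, nugget=nugget), intercept=500.0, seed=8,
        )
        resid = truth.soc_realized_map.values - truth.soc_mean_map.values
        res = sampled_variogram(resid, n=2500, max_d=1500.0, bins=15)
        occ = res.n_pairs > 30
        # iid noise: semivariance == variance = nugget at every lag
        np.testing.assert_allclose(res.gamma[occ], nugget, rtol=0.15)

    def test_negative_draws_truncated_and_counted(self):
        stack = self._unit_stack()
        truth = simulate_soc_truth(
            stack, {"elev": 0.0}, {"soil": {1: 0.0, 2: 0.0, 3: 0.0}},
            NoiseParams(partial_sill=0.0, nugget=100.0), intercept=1.0, seed=0,
        )
        assert truth.truncated_cells > 0
        assert (truth.soc_realized_map.values >= 0.0).all()


class TestGaussianFieldRecovery:
    @pytest.mark.parametrize("seed", [0, 7])
    def test_variogram_recovers_sill_and_range(self, seed):
        psill, rng_m = 400.0, 600.0
        field = gaussian_field((256, 256), 30.0, psill, rng_m, np.random.default_rng(seed))
        res = sampled_variogram(field, n=2500, max_d=1800.0, bins=30)
        occ = np.isfinite(res.gamma)

        def model(h, s, r):
            return s * (1.0 - np.exp(-3.0 * h / r))

        (s_hat, r_hat), _ = curve_fit(
            model, res.bin_centers[occ], res.gamma[occ],
            p0=[np.nanmax(res.gamma), 500.0], maxfev=10000,
        )
        assert s_hat == pytest.approx(psill, rel=0.20)
        assert r_hat == pytest.approx(rng_m, rel=0.30)


class TestSamplePlots:
    def _mask(self, n=128):
        return make_raster(np.ones((n, n)))

    def test_square_template_geometry(self):
        plots = sample_plots(
            self._mask(), None, n_clusters=1, plots_per_cluster=4,
            within_spacing_m=150.0, min_cluster_sep_m=0.0, seed=0,
        )
        assert len(plots) == 4
        xy = plots[["x", "y"]].to_numpy()
        d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
        assert d.max() <= 2 * 150.0 * np.sqrt(2) + 1e-9
        assert d[d > 0].min() == pytest.approx(150.0)

    def test_cluster_separation_enforced(self):
        plots = sample_plots(
            self._mask(), None, n_clusters=5, min_cluster_sep_m=1200.0, seed=3
        )
        centers = plots.groupby("cluster_id")[["x", "y"]].first().to_numpy()
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                assert np.hypot(*(centers[i] - centers[j])) >= 1200.0

    def test_seeded_determinism(self):
        a = sample_plots(self._mask(), None, 3, min_cluster_sep_m=600.0, seed=9)
        b = sample_plots(self._mask(), None, 3, min_cluster_sep_m=600.0, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_infeasible_separation_reports_achieved(self):
        with pytest.raises(RasterError, match="placed"):
            sample_plots(
                self._mask(64), None, n_clusters=50, min_cluster_sep_m=3000.0,
                seed=0, max_tries_per_cluster=50,
            )

    def test_soc_filled_from_realized_map(self):
        mask = self._mask(96)
        soc = mask.like(np.random.default_rng(0).uniform(10, 100, (96, 96)))
        plots = sample_plots(mask, soc, 2, min_cluster_sep_m=500.0, seed=1)
        for _, row in plots.iterrows():
            assert row["soc_t_ha"] == soc.value_at(row["x"], row["y"])


class TestGenerativeSelfConsistency:
    @pytest.mark.parametrize("seed", [4, 5])
    def test_linear_regression_recovers_identifiable_signs(self, seed):
        # 100 clusters, full inventory geometry; covariates that carry
        # independent variation (elevation, access proxies) must come back
        # with the generative sign and magnitude order
        land = make_landscape(
            n_rows=640, n_cols=640, cell_size_m=120.0, n_clusters=100,
            min_cluster_sep_m=4000.0, seed=seed, with_terrain=False,
            noise=NoiseParams(225.0, 2000.0, 100.0),
        )
        design = extract_at_plots(land.stack, land.plots)
        cont = land.stack.continuous_names()
        dummies = [
            pd.get_dummies(design[c].astype(int), prefix=c, drop_first=True, dtype=float)
            for c in land.stack.categorical_names()
        ]
        X = pd.concat([design[cont]] + dummies, axis=1)
        from sklearn.linear_model import LinearRegression

        lr = LinearRegression().fit(X.to_numpy(), land.plots["soc_t_ha"].to_numpy())
        coefs = dict(zip(X.columns, lr.coef_))
        truth = land.truth.coefficients
        for name in ("elevation", "edge_distance", "cost_surface"):
            assert np.sign(coefs[name]) == np.sign(truth[name]), name
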