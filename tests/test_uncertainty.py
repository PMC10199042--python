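"""Gridded prediction, sensitivity, percent error and stock totals."""

import numpy as np
import pandas as pd
import pytest

from socmap.cv import make_spatial_folds
from socmap.plots import extract_at_plots
from socmap.qrf import QRFParams, QRForest
from socmap.raster import RasterError, align_stack, read_raster, write_raster
from socmap.uncertainty import (
    StockEstimate,
    UncertaintyMaps,
    national_total,
    percent_error_map,
    predict_map,
    sensitivity_map,
)

from conftest import make_raster


def small_problem(seed=0, n=40):
    rng = np.random.default_rng(seed)
    grid = rng.uniform(0, 10, (12, 12))
    stack = align_stack({"x0": make_raster(grid, x0=0.0, y0=360.0)})
    mask = make_raster(np.ones((12, 12)), x0=0.0, y0=360.0)
    X = pd.DataFrame({"x0": rng.uniform(0, 10, n)})
    y = 5.0 * X["x0"].to_numpy() + rng.normal(0, 2, n)
    return stack, mask, X, y


class TestPredictMap:
    def test_single_leaf_forest_gives_constant_maps(self):
        stack, mask, X, y = small_problem()
        f = QRForest(QRFParams(n_trees=1, min_node_size=999, seed=1)).fit(X, y)
        mean_r, sd_r = predict_map(f, stack, mask)
        y_inbag = y[f.inbag_[0]]
        assert np.allclose(mean_r.valid_values(), np.mean(y_inbag))
        assert np.allclose(sd_r.valid_values(), np.std(y_inbag))

    def test_masked_out_cells_are_nodata(self):
        stack, mask, X, y = small_problem(seed=1)
        m = mask.values.copy()
        m[:6, :] = 0.0
        mask2 = mask.like(m)
        f = QRForest(QRFParams(n_trees=5, seed=0)).fit(X, y)
        mean_r, _ = predict_map(f, stack, mask2)
        assert not mean_r.mask[:6, :].any()
        assert mean_r.mask[6:, :].all()

    def test_training_cells_reproduce_point_predictions(self):
        # plots at cell centres: the map value at a plot's cell must equal
        # predict_mean_sd on the extracted design row (same code path)
        stack, mask, _, _ = small_problem(seed=2)
        plots = pd.DataFrame(
            {
                "plot_id": [f"p{i}" for i in range(6)],
                "cluster_id": "c1",
                "x": [15.0 + 30.0 * i for i in range(6)],
                "y": [360.0 - 15.0 - 30.0 * i for i in range(6)],
                "soc_t_ha": 1.0,
            }
        )
        design = extract_at_plots(stack, plots)[["x0"]]
        rng = np.random.default_rng(3)
        y = 3.0 * design["x0"].to_numpy() + rng.normal(0, 1, 6)
        f = QRForest(QRFParams(n_trees=10, min_node_size=2, seed=2)).fit(design, y)
        mean_r, sd_r = predict_map(f, stack, mask)
        mean_pt, sd_pt = f.predict_mean_sd(design)
        for i, (_, row) in enumerate(plots.iterrows()):
            assert mean_r.value_at(row.x, row.y) == mean_pt[i]
            assert sd_r.value_at(row.x, row.y) == sd_pt[i]

    def test_missing_covariate_rejected(self):
        stack, mask, X, y = small_problem(seed=3)
        f = QRForest(QRFParams(n_trees=3, seed=0)).fit(
            X.rename(columns={"x0": "other"}), y
        )
        with pytest.raises(RasterError, match="other"):
            predict_map(f, stack, mask)


class TestSensitivityMap:
    def test_per_cell_sd_matches_direct_oracle(self):
        stack, mask, _, _ = small_problem(seed=4)
        rng = np.random.default_rng(4)
        rows = []
        for c in range(6):
            for p in range(3):
                rows.append(
                    {
                        "plot_id": f"c{c}p{p}",
                        "cluster_id": f"c{c}",
                        "x": rng.uniform(0, 360),
                        "y": rng.uniform(0, 360),
                        "soc_t_ha": 0.0,
                    }
                )
        plots = pd.DataFrame(rows)
        design = extract_at_plots(stack, plots)[["x0"]]
        plots["soc_t_ha"] = 4.0 * design["x0"].to_numpy() + rng.normal(0, 1, len(plots))
        folds = make_spatial_folds(plots, k=3, seed=0)
        params = QRFParams(n_trees=8, seed=5)
        with pytest.warns(UserWarning, match="10"):
            sens = sensitivity_map(plots, design, stack, folds, params, mask)

        # oracle: refit the k fold-forests directly and take the sample SD
        maps = []
        for fold in range(folds.k):
            tr = folds.train_indices(fold)
            f = QRForest(params=params).fit(design.iloc[tr], plots["soc_t_ha"].to_numpy()[tr])
            mean_r, _ = predict_map(f, stack, mask)
            maps.append(mean_r.values)
        oracle = np.std(np.stack(maps), axis=0, ddof=1)
        np.testing.assert_allclose(sens.valid_values(), oracle[sens.mask], rtol=1e-9)
        assert (sens.valid_values() >= 0).all()


class TestPercentError:
    def test_worked_arithmetic(self):
        mean = make_raster(np.full((2, 2), 100.0))
        msd = make_raster(np.full((2, 2), 10.0))
        ssd = make_raster(np.full((2, 2), 5.0))
        out = percent_error_map(mean, msd, ssd)
        assert np.allclose(out.values, 15.0)

    def test_zero_errors_give_zero_percent(self):
        mean = make_raster(np.full((2, 2), 50.0))
        zero = make_raster(np.zeros((2, 2)))
        assert np.allclose(percent_error_map(mean, zero, zero).values, 0.0)

    def test_halving_mean_doubles_percent_error(self):
        rng = np.random.default_rng(5)
        mean = make_raster(rng.uniform(50, 150, (4, 4)))
        msd = make_raster(rng.uniform(1, 10, (4, 4)))
        ssd = make_raster(rng.uniform(1, 10, (4, 4)))
        a = percent_error_map(mean, msd, ssd).values
        b = percent_error_map(mean.like(mean.values / 2), msd, ssd).values
        np.testing.assert_allclose(b, 2 * a)

    def test_floor_cells_become_nodata(self):
        mean = make_raster(np.array([[100.0, 0.5]]))
        sd = make_raster(np.array([[10.0, 10.0]]))
        out = percent_error_map(mean, sd, sd, mean_floor=1.0)
        assert out.values[0, 1] == out.nodata
        assert out.values[0, 0] == pytest.approx(20.0)

    def test_elementwise_recomputation_oracle(self):
        rng = np.random.default_rng(6)
        mean = make_raster(rng.uniform(10, 100, (5, 5)))
        msd = make_raster(rng.uniform(0, 20, (5, 5)))
        ssd = make_raster(rng.uniform(0, 5, (5, 5)))
        out = percent_error_map(mean, msd, ssd).values
        expected = 100.0 * (msd.values + ssd.values) / mean.values
        np.testing.assert_allclose(out, expected, rtol=1e-12)


def uniform_maps(value=75.0, n_cells=1000, msd=0.0, ssd=0.0, cell=30.0):
    shape = (n_cells // 25, 25)
    mk = lambda v: make_raster(np.full(shape, v), cell_size=cell)
    mean, a, b = mk(value), mk(msd), mk(ssd)
    return UncertaintyMaps(mean, a, b, percent_error_map(mean, a, b))


class TestNationalTotal:
    def test_hand_arithmetic_uniform_map(self):
        # 1000 cells x 0.09 ha x 75 t/ha = 6750 t = 0.00675 Mt
        est = national_total(uniform_maps())
        assert est.cell_area_ha == pytest.approx(0.09)
        assert est.total_mt == pytest.approx(0.00675)

    def test_doubling_cell_area_doubles_total(self):
        est1 = national_total(uniform_maps(), cell_area_ha=0.09)
        est2 = national_total(uniform_maps(), cell_area_ha=0.18)
        assert est2.total_mt == pytest.approx(2 * est1.total_mt)

    def test_se_modes(self):
        maps = uniform_maps(value=100.0, msd=10.0, ssd=5.0)
        ind = national_total(maps, se_mode="independence")
        cor = national_total(maps, se_mode="correlated")
        n = ind.cell_count
        assert cor.se_mt == pytest.approx(ind.se_mt * np.sqrt(n), rel=1e-9)
        assert cor.se_percent == pytest.approx(15.0)  # same relative error per cell

    def test_empty_mask_rejected(self):
        maps = uniform_maps()
        empty = maps.mean.like(np.full(maps.mean.shape, np.nan))
        bad = UncertaintyMaps(empty, maps.model_sd, maps.sensitivity_sd, maps.percent_error)
        with pytest.raises(RasterError, match="empty"):
            national_total(bad)

    def test_total_conserved_through_file_roundtrip(self, tmp_path):
        rng = np.random.default_rng(7)
        shape = (20, 20)
        mean = make_raster(rng.uniform(5, 150, shape))
        msd = make_raster(rng.uniform(0, 30, shape))
        ssd = make_raster(rng.uniform(0, 10, shape))
        maps = UncertaintyMaps(mean, msd, ssd, percent_error_map(mean, msd, ssd))
        est_mem = national_total(maps)
        paths = {}
        for name, r in [("mean", mean), ("msd", msd), ("ssd", ssd)]:
            paths[name] = write_raster(r, tmp_path / f"{name}.asc")
        mean2 = read_raster(paths["mean"])
        msd2 = read_raster(paths["msd"])
        ssd2 = read_raster(paths["ssd"])
        maps2 = UncertaintyMaps(
            mean2, msd2, ssd2, percent_error_map(mean2, msd2, ssd2)
        )
        est_file = national_total(maps2)
        # bit-for-bit: fixed row-major compensated summation + exact text I/O
        assert est_file.total_mt == est_mem.total_mt
        assert est_file.se_mt == est_mem.se_mt
        assert est_file.se_percent == est_mem.se_percent
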