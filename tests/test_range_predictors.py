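"""Range-derived predictors: migration measures, day length, raster sampling."""

import numpy as np
import pytest
from shapely.geometry import box

from moltpath import range_predictors as rp


def rect(lat_lo, lat_hi, lon_lo=0.0, lon_hi=10.0):
    return box(lon_lo, lat_lo, lon_hi, lat_hi)


class TestMigrationMeasures:
    def test_nonmigrant_all_zero(self):
        rng = rp.SeasonalRange(rect(40, 50), rect(40, 50))
        assert rng.migrant_class == "nonmigrant"
        assert np.allclose(rp.migration_distance_measures(rng), 0.0)

    def test_midlatitude_measure(self):
        rng = rp.SeasonalRange(rect(40, 50), rect(0, 10, lon_lo=20, lon_hi=30))
        m = rp.migration_distance_measures(rng)
        assert m[0] == pytest.approx(40.0)   # midlats 45 vs 5
        assert m[1] == pytest.approx(40.0)   # max lats 50 vs 10
        assert m[2] == pytest.approx(40.0)
        assert m[3] == pytest.approx(50.0)   # max breeding - min nonbreeding
        assert m[4] == pytest.approx(30.0)

    def test_great_circle_quarter_circumference(self):
        # centroids a quarter of the equator apart: pi/2 * 6371 km
        b = box(-0.5, -0.5, 0.5, 0.5)
        n = box(89.5, -0.5, 90.5, 0.5)
        rng = rp.SeasonalRange(b, n)
        m = rp.migration_distance_measures(rng)
        assert m[5] == pytest.approx(np.pi / 2 * 6371.0, rel=1e-3)

    def test_partial_migrant_not_zeroed(self):
        rng = rp.SeasonalRange(rect(0, 20), rect(10, 30))
        assert rng.migrant_class == "partial"
        assert rp.migration_distance_measures(rng)[0] > 0


class TestRepresentativeMeasure:
    def test_identical_columns_tie_to_first(self):
        M = np.tile(np.arange(10.0)[:, None], (1, 6))
        res = rp.select_representative_measure(M)
        assert res["selected"] == 0
        assert np.allclose(res["mean_r2"], 1.0)

    def test_noise_column_not_selected(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=50)
        M = np.column_stack([base + 0.05 * rng.normal(size=50) for _ in range(5)]
                            + [rng.normal(size=50)])
        assert rp.select_representative_measure(M)["selected"] != 5

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        M = rng.normal(size=(30, 4)) + rng.normal(size=(30, 1))
        sel = rp.select_representative_measure(M)["selected"]
        M2 = M.copy()
        M2[:, 1] = 100.0 * M2[:, 1] - 7.0
        assert rp.select_representative_measure(M2)["selected"] == sel

    def test_constant_column_excluded(self):
        rng = np.random.default_rng(3)
        M = rng.normal(size=(20, 3))
        M[:, 2] = 5.0
        res = rp.select_representative_measure(M)
        assert res["excluded_constant"] == [2]
        assert res["selected"] != 2


class TestDayLength:
    def test_equator_near_twelve(self):
        for day in (1, 80, 172, 266, 355):
            assert rp.day_length_analytic(0.0, day) == pytest.approx(12.0, abs=0.2)

    def test_polar_day(self):
        assert rp.day_length_analytic(80.0, 172) == pytest.approx(24.0)

    def test_polar_night(self):
        assert rp.day_length_analytic(80.0, 355) == pytest.approx(0.0)

    @pytest.mark.parametrize("lat", [-50, -30, 0, 30, 45, 50])
    def test_annual_mean_twelve_hours_midlatitudes(self, lat):
        assert rp.mean_day_length(lat) == pytest.approx(12.0, abs=0.1)

    @pytest.mark.parametrize("lat", [-80, -65, 65, 80])
    def test_annual_mean_near_poles_slightly_asymmetric(self, lat):
        # the orbital-anomaly term makes northern summers longer, so the
        # annual mean drifts from 12 h toward the poles but stays bounded
        assert rp.mean_day_length(lat) == pytest.approx(12.0, abs=0.3)

    def test_breeding_window_longer_in_north(self):
        assert (rp.mean_day_length(50, rp.BREEDING_MONTHS)
                > rp.mean_day_length(0, rp.BREEDING_MONTHS))


class TestRasterSampling:
    def test_constant_raster_exact(self):
        raster = rp.GridRaster(np.full((10, 10), 7.0), 0, 0, 1, 1)
        res = rp.sample_raster_mean(box(2, 2, 8, 8), raster, n_points=500, seed=0)
        assert res["mean"] == pytest.approx(7.0)
        assert res["n_nodata"] == 0

    def test_latitude_gradient_mean(self):
        # cell value = latitude of cell center; rectangle lat 0-10 -> mean 5
        raster = rp.GridRaster.from_function(lambda x, y: y, (0, 0, 10, 10), (200, 200))
        res = rp.sample_raster_mean(box(0, 0, 10, 10), raster, n_points=4000, seed=1)
        se = 10 / np.sqrt(12) / np.sqrt(4000)
        assert abs(res["mean"] - 5.0) < 3 * se + 0.05  # + half cell size

    def test_two_seeds_agree_within_monte_carlo_error(self):
        raster = rp.GridRaster.from_function(lambda x, y: y, (0, 0, 10, 10), (100, 100))
        m1 = rp.sample_raster_mean(box(0, 0, 10, 10), raster, 2000, seed=1)["mean"]
        m2 = rp.sample_raster_mean(box(0, 0, 10, 10), raster, 2000, seed=2)["mean"]
        sd = 10 / np.sqrt(12)
        assert abs(m1 - m2) < 3 * sd / np.sqrt(2000) * np.sqrt(2)

    def test_reproducible_given_seed(self):
        raster = rp.GridRaster.from_function(lambda x, y: x * y, (0, 0, 5, 5), (50, 50))
        a = rp.sample_raster_mean(box(1, 1, 4, 4), raster, 1000, seed=9)
        b = rp.sample_raster_mean(box(1, 1, 4, 4), raster, 1000, seed=9)
        assert a["mean"] == b["mean"]

    def test_disjoint_extent_raises(self):
        raster = rp.GridRaster(np.ones((5, 5)), 0, 0, 1, 1)
        with pytest.raises(ValueError, match="intersect"):
            rp.sample_raster_mean(box(100, 100, 110, 110), raster, 100, seed=0)


class TestSolarExposure:
    def test_products(self):
        assert rp.solar_exposure(0.0, 5.0) == 0.0
        assert rp.solar_exposure(2.0, 3.0) == 6.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rp.solar_exposure(-1.0, 2.0)

    def test_mean_of_products_differs_from_product_of_means(self):
        r = np.array([1.0, 3.0])
        d = np.array([3.0, 1.0])
        assert rp.solar_exposure(r, d).mean() != pytest.approx(r.mean() * d.mean())


def test_predictor_table_smoke():
    ranges = {
        "mig": rp.SeasonalRange(rect(40, 50), rect(0, 10, lon_lo=20, lon_hi=30)),
        "res": rp.SeasonalRange(rect(0, 10), rect(0, 10)),
    }
    table = rp.predictor_table(ranges, n_points=500, seed=0)
    assert table.loc["res", "migration_distance"] == 0.0
    assert table.loc["mig", "migration_distance"] == pytest.approx(40.0)
    assert 0 < table.loc["mig", "day_length"] <= 24
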