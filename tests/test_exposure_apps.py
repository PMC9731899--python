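"""Regulatory arithmetic, population weighting, heat co-occurrence, areal links."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from aerosurf import exposure_apps as xa
from aerosurf.synthetic_data import PopulationRaster


def make_surface(dates, values, cell_ids=None, kind="daily_mean"):
    values = np.asarray(values, float)
    cell_ids = np.arange(values.shape[1]) if cell_ids is None else cell_ids
    return xa.ExposureSurface(pd.DatetimeIndex(dates), np.asarray(cell_ids),
                              values, kind)


class TestRegulatoryAnnualMean:
    def test_constant_series(self):
        dates = pd.date_range("2018-01-01", "2018-12-31")
        assert xa.regulatory_annual_mean(dates, np.full(len(dates), 7.5)) == 7.5

    def test_mean_of_four_quarterly_means(self):
        # quarters valued 10,10,10,22 with very different day counts
        dates = pd.DatetimeIndex(
            ["2018-01-01", "2018-04-01", "2018-04-02", "2018-04-03",
             "2018-07-01", "2018-10-01", "2018-10-02"]
        )
        vals = np.array([10, 10, 10, 10, 10, 22, 22], float)
        assert xa.regulatory_annual_mean(dates, vals) == pytest.approx(13.0)

    def test_differs_from_plain_mean_on_unbalanced_year(self):
        dates = pd.date_range("2018-01-01", periods=10).append(
            pd.date_range("2018-04-01", periods=90)
        ).append(pd.date_range("2018-07-01", periods=90)).append(
            pd.date_range("2018-10-01", periods=90)
        )
        vals = np.concatenate([np.full(10, 40.0), np.full(270, 10.0)])
        reg = xa.regulatory_annual_mean(dates, vals)
        plain = vals.mean()
        assert reg == pytest.approx(17.5)
        assert plain == pytest.approx(11.0714285714, rel=1e-9)
        assert reg != pytest.approx(plain)

    def test_empty_quarter_is_missing(self):
        dates = pd.date_range("2018-01-01", "2018-06-30")
        assert np.isnan(xa.regulatory_annual_mean(dates, np.ones(len(dates))))

    def test_equal_quarters_match_plain_mean(self):
        rng = np.random.default_rng(0)
        dates = pd.DatetimeIndex(
            [f"2018-{m:02d}-{d:02d}" for m in (2, 5, 8, 11) for d in range(1, 11)]
        )
        vals = rng.uniform(5, 50, len(dates))
        assert xa.regulatory_annual_mean(dates, vals) == pytest.approx(vals.mean())


class TestPopulateCells:
    def test_cell_inside_one_raster_cell(self):
        raster = PopulationRaster(0, 0, 1000, 1000, np.full((3, 3), 123.0))
        cells = pd.DataFrame({"cell_id": [0], "x": [1500.0], "y": [1500.0]})
        got = xa.populate_cells(cells, 500.0, raster)
        assert got["density"].iloc[0] == pytest.approx(123.0)
        assert got["persons"].iloc[0] == pytest.approx(123.0 * 0.25)

    def test_straddling_two_cells_equal_halves(self):
        density = np.array([[100.0, 300.0]])
        raster = PopulationRaster(0, 0, 1000, 1000, density)
        cells = pd.DataFrame({"cell_id": [0], "x": [1000.0], "y": [500.0]})
        got = xa.populate_cells(cells, 500.0, raster)
        assert got["density"].iloc[0] == pytest.approx(200.0)

    def test_gap_under_cell_is_error(self):
        raster = PopulationRaster(0, 0, 1000, 1000, np.full((2, 2), 1.0))
        cells = pd.DataFrame({"cell_id": [0], "x": [2100.0], "y": [500.0]})
        with pytest.raises(ValueError, match="gap"):
            xa.populate_cells(cells, 500.0, raster)

    def test_matches_subdivision_oracle(self, small_dataset):
        fx = small_dataset.fixture
        got = xa.populate_cells(fx.cells, fx.cell_size, fx.population)
        rng = np.random.default_rng(0)
        idx = rng.choice(len(fx.cells), size=5, replace=False)
        xe, ye = fx.population.x_edges, fx.population.y_edges
        n_sub = 500
        for i in idx:
            cx, cy = fx.cells["x"].iloc[i], fx.cells["y"].iloc[i]
            half = fx.cell_size / 2
            gx = np.linspace(cx - half, cx + half, n_sub + 1)[:-1] + fx.cell_size / (2 * n_sub)
            gy = np.linspace(cy - half, cy + half, n_sub + 1)[:-1] + fx.cell_size / (2 * n_sub)
            ix = np.searchsorted(xe, gx, side="right") - 1
            iy = np.searchsorted(ye, gy, side="right") - 1
            oracle = fx.population.density[np.ix_(iy, ix)].mean()
            assert got["density"].iloc[i] == pytest.approx(oracle, rel=1e-3)


class TestCompliance:
    def toy(self):
        # 2 cells; cell 0 exceeds on 3 days, cell 1 on 1 day
        dates = pd.date_range("2018-01-01", periods=4)
        values = np.array(
            [[50.0, 50.0], [50.0, 20.0], [50.0, 20.0], [20.0, 20.0]]
        )
        surface = make_surface(dates, values)
        pops = pd.DataFrame({"cell_id": [0, 1], "persons": [100.0, 200.0]})
        return surface, pops

    def test_person_days_arithmetic(self):
        surface, pops = self.toy()
        # only daily quantities meaningful here; bypass annual by computing directly
        _, total = xa._person_days(surface, pops["persons"].to_numpy(), 41.0)
        assert total == 100 * 3 + 200 * 1 == 500
        days_per_cell, _ = xa._person_days(surface, pops["persons"].to_numpy(), 41.0)
        weighted = pops["persons"].to_numpy() @ days_per_cell / 300.0
        assert weighted == pytest.approx(5 / 3)

    def test_all_below_limits_gives_zero(self):
        dates = pd.date_range("2018-01-01", "2018-12-31")
        surface = make_surface(dates, np.full((len(dates), 2), 5.0))
        pops = pd.DataFrame({"cell_id": [0, 1], "persons": [10.0, 20.0]})
        rep = xa.compliance_report(surface, pops)["model"]
        assert rep["person_days_exceedance"] == 0
        assert rep["frac_above_annual"] == 0
        assert rep["mean_exceedance_days_weighted"] == 0

    def test_person_days_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        dates = pd.date_range("2018-01-01", "2018-12-31")
        values = rng.lognormal(np.log(25), 0.5, (len(dates), 9))
        surface = make_surface(dates, values)
        persons = rng.uniform(0, 500, 9)
        pops = pd.DataFrame({"cell_id": np.arange(9), "persons": persons})
        rep = xa.compliance_report(surface, pops)["model"]
        oracle = 0.0
        for c in range(9):
            for d in range(len(dates)):
                if values[d, c] > 41.0:
                    oracle += persons[c]
        assert rep["person_days_exceedance"] == pytest.approx(oracle, rel=1e-12)

    def test_additive_over_disjoint_date_ranges(self):
        surface, pops = self.toy()
        p = pops["persons"].to_numpy()
        _, total = xa._person_days(surface, p, 41.0)
        first = make_surface(surface.dates[:2], surface.values[:2])
        second = make_surface(surface.dates[2:], surface.values[2:])
        _, t1 = xa._person_days(first, p, 41.0)
        _, t2 = xa._person_days(second, p, 41.0)
        assert total == t1 + t2


class TestPopulationEcdf:
    def test_degenerate_distribution(self):
        dates = pd.date_range("2018-01-01", "2018-12-31")
        surface = make_surface(dates, np.full((len(dates), 3), 12.0))
        pops = pd.DataFrame({"cell_id": [0, 1, 2], "persons": [1.0, 2.0, 3.0]})
        ecdf = xa.population_ecdf(surface, pops, 2018)
        assert xa.weighted_quantile(ecdf, 0.1) == pytest.approx(12.0)
        assert ecdf["cum_frac"].iloc[-1] == pytest.approx(1.0)

    def test_two_point_mass(self):
        dates = pd.date_range("2018-01-01", "2018-12-31")
        values = np.tile([10.0, 30.0], (len(dates), 1))
        surface = make_surface(dates, values)
        pops = pd.DataFrame({"cell_id": [0, 1], "persons": [5.0, 5.0]})
        ecdf = xa.population_ecdf(surface, pops, 2018)
        assert ecdf["cum_frac"].tolist() == pytest.approx([0.5, 1.0])
        assert xa.weighted_quantile(ecdf, 0.5) == 10.0
        assert xa.weighted_quantile(ecdf, 0.51) == 30.0

    def test_monotone_right_continuous(self):
        rng = np.random.default_rng(1)
        dates = pd.date_range("2018-01-01", "2018-12-31")
        surface = make_surface(dates, rng.lognormal(3, 0.4, (len(dates), 20)))
        pops = pd.DataFrame({"cell_id": np.arange(20),
                             "persons": rng.uniform(1, 100, 20)})
        ecdf = xa.population_ecdf(surface, pops, 2018)
        assert (np.diff(ecdf["cum_frac"]) >= 0).all()
        assert (np.diff(ecdf["concentration"]) >= 0).all()

    def test_quantiles_match_person_expansion_oracle(self):
        rng = np.random.default_rng(2)
        dates = pd.date_range("2018-01-01", "2018-12-31")
        surface = make_surface(dates, rng.lognormal(3, 0.4, (len(dates), 6)))
        persons = rng.integers(1, 50, 6)
        pops = pd.DataFrame({"cell_id": np.arange(6), "persons": persons.astype(float)})
        ecdf = xa.population_ecdf(surface, pops, 2018)
        from aerosurf.exposure_apps import annual_mean_surface
        annual = annual_mean_surface(surface, 2018)
        expanded = np.sort(np.repeat(annual, persons))
        for q in (0.1, 0.25, 0.5, 0.9):
            oracle = expanded[max(0, int(np.ceil(q * len(expanded))) - 1)]
            assert xa.weighted_quantile(ecdf, q) == pytest.approx(oracle)


class TestDailyRatio:
    def test_proportional_surfaces(self):
        dates = pd.date_range("2018-06-01", periods=4)
        mean = make_surface(dates, np.full((4, 3), 10.0))
        mx = make_surface(dates, np.full((4, 3), 20.0), kind="daily_max")
        precip = np.array([[0, 0, 0], [2, 2, 2], [0, 0, 0], [3, 3, 3]], float)
        out = xa.daily_ratio_series(mean, mx, precip)
        assert (out["series"]["ratio"] == 2.0).all()
        assert out["mean_ratio_dry"] == 2.0 and out["mean_ratio_rainy"] == 2.0

    def test_hand_grouped_six_day_toy(self):
        dates = pd.date_range("2018-06-01", periods=6)
        mean_vals = np.outer([10, 10, 20, 20, 10, 40], [1.0, 1.0])
        max_vals = np.outer([15, 25, 30, 50, 21, 60], [1.0, 1.0])
        precip = np.outer([0, 2, 0, 5, 0, 1], [1.0, 1.0])
        out = xa.daily_ratio_series(
            make_surface(dates, mean_vals),
            make_surface(dates, max_vals, kind="daily_max"), precip,
        )
        # dry days: ratios 1.5, 1.5, 2.1 -> 1.7; rainy: 2.5, 2.5, 1.5 -> ~2.1667
        assert out["mean_ratio_dry"] == pytest.approx((1.5 + 1.5 + 2.1) / 3)
        assert out["mean_ratio_rainy"] == pytest.approx((2.5 + 2.5 + 1.5) / 3)

    def test_ratio_at_least_one_from_shared_truth(self, small_dataset):
        truth = small_dataset.truth
        mean = make_surface(truth.dates, truth.mean, truth.cell_ids)
        mx = make_surface(
            truth.dates, truth.mean * truth.hourly_profile.max(axis=1)[:, None],
            truth.cell_ids, kind="daily_max",
        )
        out = xa.daily_ratio_series(
            mean, mx, small_dataset.predictors.daily["precipitation"]
        )
        assert (out["series"]["ratio"] >= 1.0).all()


def brute_kendall(x, y):
    """O(n^2) tau-b oracle from the pair-count definition."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = x[i] - x[j], y[i] - y[j]
            if a == 0 and b == 0:
                continue
            elif a == 0:
                tx += 1
            elif b == 0:
                ty += 1
            elif a * b > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / np.sqrt((n0 - count_ties(x)) * (n0 - count_ties(y)))


def count_ties(v):
    from collections import Counter
    return sum(c * (c - 1) / 2 for c in Counter(v).values())


class TestKendall:
    def test_perfect_concordance_discordance(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert xa.kendall_tau(x, x) == pytest.approx(1.0)
        assert xa.kendall_tau(x, x[::-1]) == pytest.approx(-1.0)

    def test_single_swap(self):
        assert xa.kendall_tau([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(2 / 3)

    def test_tied_example_matches_pair_count_oracle(self):
        x, y = [1.0, 2.0, 2.0, 3.0], [1.0, 2.0, 3.0, 3.0]
        assert xa.kendall_tau(x, y) == pytest.approx(brute_kendall(x, y))

    def test_symmetry_and_negation_on_tie_free_data(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=15), rng.normal(size=15)
        assert xa.kendall_tau(x, y) == pytest.approx(xa.kendall_tau(y, x))
        assert xa.kendall_tau(x, -y) == pytest.approx(-xa.kendall_tau(x, y))

    def test_all_tied_is_missing(self):
        assert np.isnan(xa.kendall_tau([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestHeatCooccurrence:
    def test_partition_conservation(self, small_dataset):
        from aerosurf.synthetic_data import temperature_celsius
        truth = small_dataset.truth
        surface = make_surface(truth.dates, truth.mean, truth.cell_ids)
        temp = temperature_celsius(small_dataset.predictors)
        out = xa.heat_cooccurrence(surface, temp)
        assert out["n_exceedance_cell_days"] <= out["n_cell_days"]
        assert out["n_cell_days"] == truth.mean.size

    def test_planted_positive_coupling_raises_hot_day_pm(self):
        from aerosurf import synthetic_data as sd
        cfg = sd.SyntheticConfig(nx=10, ny=10, n_stations=3, n_years=1,
                                 temp_pm_coupling=2.0, seed=21)
        fx = sd.make_fixture(cfg)
        truth = sd.make_truth(fx, cfg)
        pred = sd.simulate_predictors(fx, truth, config=cfg)
        surface = make_surface(truth.dates, truth.mean, truth.cell_ids)
        out = xa.heat_cooccurrence(surface, sd.temperature_celsius(pred))
        assert out["median_pm_hot"] > out["median_pm_other"]
        assert out["tau"] > 0

    def test_conditional_quartiles_ordered(self, small_dataset):
        from aerosurf.synthetic_data import temperature_celsius
        truth = small_dataset.truth
        surface = make_surface(truth.dates, truth.mean, truth.cell_ids)
        out = xa.heat_cooccurrence(surface, temperature_celsius(small_dataset.predictors))
        q = out["conditional_quartiles"].dropna()
        assert (q["q25"] <= q["q50"]).all() and (q["q50"] <= q["q75"]).all()


def ray_cast(poly_coords, px, py):
    """Independent even-odd ray-casting point-in-polygon test."""
    inside = False
    n = len(poly_coords)
    for i in range(n):
        x1, y1 = poly_coords[i]
        x2, y2 = poly_coords[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


class TestArealLink:
    def surface(self, cells):
        dates = pd.date_range("2018-01-01", "2018-12-31")
        values = np.tile(np.arange(len(cells), dtype=float) * 10 + 20,
                         (len(dates), 1))
        return make_surface(dates, values, cells["cell_id"].to_numpy())

    def test_two_centroid_mean(self):
        cells = pd.DataFrame({"cell_id": [0, 1, 2], "x": [100.0, 200.0, 900.0],
                              "y": [100.0, 100.0, 900.0]})
        surface = self.surface(cells)  # annual means 20, 30, 40
        polys = pd.DataFrame({
            "unit_id": ["P"], "geometry": [box(0, 0, 300, 300)],
            "marginalization": [0.4],
        })
        out = xa.areal_link(surface, polys, cells, 2018)
        assert out["per_polygon"]["exposure"].iloc[0] == pytest.approx(25.0)

    def test_empty_polygon_missing_and_excluded(self):
        cells = pd.DataFrame({"cell_id": [0, 1], "x": [100.0, 200.0],
                              "y": [100.0, 100.0]})
        surface = self.surface(cells)
        polys = pd.DataFrame({
            "unit_id": ["P", "Q"],
            "geometry": [box(0, 0, 300, 300), box(5000, 5000, 6000, 6000)],
            "marginalization": [0.4, 1.2],
        })
        out = xa.areal_link(surface, polys, cells, 2018)
        assert np.isnan(out["per_polygon"]["exposure"].iloc[1])

    def test_boundary_centroid_counts_inside(self):
        cells = pd.DataFrame({"cell_id": [0], "x": [300.0], "y": [150.0]})
        surface = self.surface(cells)
        polys = pd.DataFrame({"unit_id": ["P"], "geometry": [box(0, 0, 300, 300)],
                              "marginalization": [0.0]})
        out = xa.areal_link(surface, polys, cells, 2018)
        assert out["per_polygon"]["exposure"].iloc[0] == pytest.approx(20.0)

    def test_membership_matches_ray_casting_oracle(self, small_dataset):
        rng = np.random.default_rng(3)
        import shapely
        for _, row in small_dataset.fixture.polygons.iterrows():
            poly = row["geometry"]
            coords = list(poly.exterior.coords)[:-1]
            minx, miny, maxx, maxy = poly.bounds
            px = rng.uniform(minx - 500, maxx + 500, 200)
            py = rng.uniform(miny - 500, maxy + 500, 200)
            got = shapely.covers(poly, shapely.points(px, py))
            oracle = np.array([ray_cast(coords, x, y) for x, y in zip(px, py)])
            np.testing.assert_array_equal(got, oracle)

    def test_bin_means_within_exposure_range(self, small_dataset):
        truth = small_dataset.truth
        surface = make_surface(truth.dates, truth.mean, truth.cell_ids)
        out = xa.areal_link(surface, small_dataset.fixture.polygons,
                            small_dataset.fixture.cells, 2018)
        ok = out["per_polygon"]["exposure"].dropna()
        if len(ok):
            assert out["by_bin"]["mean_exposure"].between(
                ok.min() - 1e-9, ok.max() + 1e-9
            ).all()
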