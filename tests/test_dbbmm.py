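import numpy as np
import pandas as pd
import pytest
import shapely

from migtrack import dbbmm
from migtrack.dbbmm import (BridgeVariance, GridSpec, UDGrid, composite_ud,
                            compute_ud, estimate_dynamic_variance, isopleths,
                            region_areas, tabulate_region_use, weight_by_days)
from migtrack.io_formats import GPSTrack, RegionSet
from migtrack.projection import AlbersEqualArea

PROJ = AlbersEqualArea()


def brownian_track(sigma2_kmh, n, seed, dt_h=0.5, err_km=0.0, start_lonlat=(-100.0, 45.0)):
    """Pure 2-d Brownian motion in projected km, re-expressed as lon/lat."""
    rng = np.random.default_rng(seed)
    x0, y0 = PROJ.forward(*start_lonlat)
    steps = rng.normal(0.0, np.sqrt(sigma2_kmh * dt_h), (n - 1, 2))
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)]) + [x0, y0]
    if err_km:
        xy = xy + rng.normal(0, err_km, xy.shape)
    lon, lat = PROJ.inverse(xy[:, 0], xy[:, 1])
    ts = pd.date_range("2019-04-01", periods=n, freq="30min", tz="UTC")
    return GPSTrack("bb", ts, lon, lat)


def uniform_grid(vals):
    return UDGrid(0.0, 0.0, np.sqrt(10.0), np.asarray(vals, float), PROJ)


class TestDynamicVariance:
    def test_brownian_recovery_within_25pct(self):
        true = 4.0  # km^2/h
        med = []
        for s in range(20):
            tr = brownian_track(true, 200, seed=s)
            bv = estimate_dynamic_variance(tr, location_error_m=8.0)
            med.append(np.median(bv.sigma2))
        assert np.median(med) == pytest.approx(true, rel=0.25)

    def test_stationary_jitter_near_zero(self):
        tr = brownian_track(0.0, 120, seed=1, err_km=0.008)
        bv = estimate_dynamic_variance(tr, location_error_m=8.0)
        assert np.median(bv.sigma2) < 0.01

    def test_planted_variance_change_detected(self):
        rng = np.random.default_rng(3)
        n = 240
        x0, y0 = PROJ.forward(-100.0, 45.0)
        s2 = np.where(np.arange(n - 1) < n // 2, 0.25, 9.0)
        steps = rng.normal(0.0, np.sqrt(s2 * 0.5)[:, None], (n - 1, 2))
        xy = np.vstack([[0, 0], np.cumsum(steps, axis=0)]) + [x0, y0]
        lon, lat = PROJ.inverse(xy[:, 0], xy[:, 1])
        ts = pd.date_range("2019-04-01", periods=n, freq="30min", tz="UTC")
        bv = estimate_dynamic_variance(GPSTrack("x", ts, lon, lat))
        third = (n - 1) // 3
        assert np.mean(bv.sigma2[:third]) < np.mean(bv.sigma2[-third:]) / 4

    def test_short_track_falls_back_to_global(self):
        tr = brownian_track(1.0, 12, seed=2)
        bv = estimate_dynamic_variance(tr)
        assert len(np.unique(bv.sigma2)) == 1

    def test_window_margin_validation(self):
        tr = brownian_track(1.0, 60, seed=0)
        with pytest.raises(ValueError):
            estimate_dynamic_variance(tr, window=24)
        with pytest.raises(ValueError):
            estimate_dynamic_variance(tr, window=15, margin=9)


def _grid_around(track, pad=30.0):
    return GridSpec.for_tracks([track], pad_km=pad)


class TestComputeUD:
    def test_coincident_fixes_mass_in_one_cell(self):
        lon, lat = PROJ.inverse(1.5 * np.sqrt(10), 1.5 * np.sqrt(10))
        ts = pd.date_range("2019-04-01", periods=2, freq="30min", tz="UTC")
        tr = GPSTrack("x", ts, np.full(2, float(lon)), np.full(2, float(lat)))
        grid = GridSpec(0.0, 0.0, 3, 3)
        ud = compute_ud(tr, BridgeVariance(np.array([0.0])), grid)
        assert ud.values[1, 1] > 0.99

    def test_straight_bridge_stays_in_corridor(self):
        # two fixes ~9.5 km apart, small motion variance: the ridge runs
        # along the segment and mass off a 3-cell corridor is < 1%
        c = np.sqrt(10.0)
        lon0, lat0 = PROJ.inverse(0.5 * c, 1.5 * c)
        lon1, lat1 = PROJ.inverse(3.5 * c, 1.5 * c)
        ts = pd.date_range("2019-04-01", periods=2, freq="30min", tz="UTC")
        tr = GPSTrack("x", ts, np.array([lon0, lon1]), np.array([lat0, lat1]))
        grid = GridSpec(-3 * c, -3 * c, 10, 9)
        ud = compute_ud(tr, BridgeVariance(np.array([0.5])), grid)
        corridor = ud.values[3:6, :].sum()
        assert 1.0 - corridor < 0.01

    def test_normalization_exact(self):
        for s in range(3):
            tr = brownian_track(2.0, 60, seed=40 + s)
            ud = compute_ud(tr, estimate_dynamic_variance(tr), _grid_around(tr))
            assert abs(ud.values.sum() - 1.0) < 1e-9

    def test_quadrature_convergence(self):
        tr = brownian_track(2.0, 40, seed=7)
        grid = _grid_around(tr)
        bv = estimate_dynamic_variance(tr)
        u1 = compute_ud(tr, bv, grid)              # default node count
        u2 = compute_ud(tr, bv, grid, n_quadrature=48)
        assert np.abs(u1.values - u2.values).max() < 1e-4


class TestWeighting:
    def test_residence_cell_mass_increases(self):
        tr = brownian_track(0.05, 100, seed=11)
        grid = _grid_around(tr)
        ud = compute_ud(tr, estimate_dynamic_variance(tr), grid)
        w = weight_by_days(ud, tr)
        x, y = PROJ.forward(tr.lon, tr.lat)
        col, row = grid.cell_of(x, y)
        vals, counts = np.unique(np.stack([row, col]), axis=1, return_counts=True)
        r, c = vals[:, np.argmax(counts)]
        assert w.values[r, c] >= ud.values[r, c]

    def test_fix_day_ratio_ten_to_one(self):
        # two cells with equal prior mass; 10 distinct fix-days vs 1
        c = np.sqrt(10.0)
        lon0, lat0 = PROJ.inverse(0.5 * c, 0.5 * c)
        lon1, lat1 = PROJ.inverse(1.5 * c, 0.5 * c)
        times = [pd.Timestamp(f"2019-04-{d:02d}T00:00", tz="UTC") for d in range(1, 11)]
        times.append(pd.Timestamp("2019-04-11T00:00", tz="UTC"))
        tr = GPSTrack("x", pd.DatetimeIndex(times),
                      np.array([lon0] * 10 + [lon1]),
                      np.array([lat0] * 10 + [lat1]))
        ud = UDGrid(0.0, 0.0, c, np.array([[0.5, 0.5]]), PROJ)
        w = weight_by_days(ud, tr)
        assert w.values[0, 0] / w.values[0, 1] == pytest.approx(10.0)

    def test_uniform_one_fix_per_cell_per_day_noop(self):
        c = np.sqrt(10.0)
        lons, lats = [], []
        for k in range(4):
            lon, lat = PROJ.inverse((k + 0.5) * c, 0.5 * c)
            lons.append(float(lon))
            lats.append(float(lat))
        times = pd.DatetimeIndex(
            [pd.Timestamp(f"2019-04-{d:02d}T00:00", tz="UTC") for d in range(1, 5)])
        tr = GPSTrack("x", times, np.array(lons), np.array(lats))
        ud = UDGrid(0.0, 0.0, c, np.full((1, 4), 0.25), PROJ)
        w = weight_by_days(ud, tr)
        np.testing.assert_allclose(w.values, ud.values, atol=1e-12)


class TestComposite:
    def test_single_ud_identity(self):
        u = uniform_grid([[0.5, 0.5]])
        np.testing.assert_allclose(composite_ud([u]).values, u.values)

    def test_two_disjoint_uds_half_each(self):
        a = uniform_grid([[1.0, 0.0]])
        b = uniform_grid([[0.0, 1.0]])
        comp = composite_ud([a, b])
        np.testing.assert_allclose(comp.values, [[0.5, 0.5]])

    def test_n_identical_idempotent(self):
        u = uniform_grid([[0.3, 0.7]])
        comp = composite_ud([u] * 5)
        np.testing.assert_allclose(comp.values, u.values)

    def test_grid_mismatch_rejected(self):
        a = uniform_grid([[1.0]])
        b = UDGrid(5.0, 0.0, np.sqrt(10.0), np.array([[1.0]]), PROJ)
        with pytest.raises(ValueError, match="align"):
            composite_ud([a, b])


class TestIsopleths:
    def test_uniform_four_cells_half_level(self):
        iso = isopleths(uniform_grid([[0.25, 0.25], [0.25, 0.25]]), [0.5])
        assert iso.mask(0.5).sum() == 2

    def test_single_cell_all_levels(self):
        iso = isopleths(uniform_grid([[1.0, 0.0], [0.0, 0.0]]))
        for level, mask in iso.masks.items():
            assert mask.sum() == 1

    def test_minimal_mass_against_bruteforce(self):
        rng = np.random.default_rng(21)
        vals = rng.random(100)
        vals /= vals.sum()
        iso = isopleths(uniform_grid(vals.reshape(10, 10)), [0.9])
        mask = iso.mask(0.9)
        mass = vals.reshape(10, 10)[mask].sum()
        assert mass >= 0.9
        # minimality under the tie rule: dropping the smallest included cell
        # must fall below the level
        included = np.sort(vals.reshape(10, 10)[mask])
        assert mass - included[0] < 0.9

    def test_nesting(self):
        rng = np.random.default_rng(22)
        vals = rng.random((12, 12)) ** 3
        vals /= vals.sum()
        iso = isopleths(uniform_grid(vals))
        levels = sorted(iso.masks)
        for a, b in zip(levels, levels[1:]):
            assert (iso.mask(a) <= iso.mask(b)).all()


def _square_region(x0, y0, x1, y1):
    """Axis-aligned projected-km box as a lon/lat polygon."""
    xs = np.linspace(x0, x1, 20)
    ys = np.linspace(y0, y1, 20)
    ring_x = np.concatenate([xs, np.full(20, x1), xs[::-1], np.full(20, x0)])
    ring_y = np.concatenate([np.full(20, y0), ys, np.full(20, y1), ys[::-1]])
    lon, lat = PROJ.inverse(ring_x, ring_y)
    return shapely.Polygon(np.column_stack([lon, lat]))


class TestRegionAreas:
    def test_single_region_holds_everything(self):
        c = np.sqrt(10.0)
        vals = np.zeros((4, 4))
        vals[1:3, 1:3] = 0.25
        iso = isopleths(UDGrid(0.0, 0.0, c, vals, PROJ))
        region = RegionSet({"R": _square_region(-1 * c, -1 * c, 5 * c, 5 * c)})
        table = region_areas(iso, region)
        row = table[table.region == "R"].iloc[0]
        assert row.high_use_pct == pytest.approx(100.0)
        assert row.high_use_rank == 1

    def test_cells_above_lat_cutoff_dropped(self):
        c = np.sqrt(10.0)
        x_hi, y_hi = PROJ.forward(-100.0, 61.0)
        x_lo, y_lo = PROJ.forward(-100.0, 50.0)
        vals = np.zeros((2, 1))
        grid = UDGrid(x_hi - c / 2, y_lo - c / 2, c, vals, PROJ)
        # cell 0 at 50 N holds half the mass, cell at 61 N the other half
        vals2 = np.array([[0.5]])
        g1 = UDGrid(x_lo - c / 2, y_lo - c / 2, c,
                    np.array([[0.5], [0.5]]), PROJ)
        # build a 2-cell column: bottom at 50N, top far enough north to pass 61N
        y61 = PROJ.forward(-100.0, 61.0)[1]
        ny = int((y61 - y_lo) / c) + 2
        vals = np.zeros((ny, 1))
        vals[0, 0] = 0.5
        vals[-1, 0] = 0.5
        grid = UDGrid(x_lo - c / 2, y_lo - c / 2, c, vals, PROJ)
        iso = isopleths(grid)
        region = RegionSet({"R": _square_region(x_lo - 5 * c, y_lo - 5 * c,
                                                x_lo + 5 * c, y61 + 5 * c)})
        table = region_areas(iso, region, lat_cutoff_deg=60.0)
        assert table.attrs["total_high_km2"] == pytest.approx(10.0)

    def test_three_to_one_split(self):
        # 8 uniform cells: the 50% mask is the first 4 (x centroids 0.5c..3.5c)
        c = np.sqrt(10.0)
        vals = np.full((1, 8), 0.125)
        iso = isopleths(UDGrid(0.0, 0.0, c, vals, PROJ))
        ra = RegionSet({
            "A": _square_region(-c, -c, 3 * c, 2 * c),
            "B": _square_region(3 * c, -c, 5 * c, 2 * c)})
        table = region_areas(iso, ra).set_index("region")
        assert table.loc["A", "high_use_pct"] == pytest.approx(75.0)
        assert table.loc["B", "high_use_pct"] == pytest.approx(25.0)
        assert table.loc["A", "high_use_rank"] == 1
        assert table.loc["B", "high_use_rank"] == 2

    def test_empty_region_set_single_unassigned_row(self):
        vals = np.array([[1.0]])
        iso = isopleths(UDGrid(0.0, 0.0, np.sqrt(10.0), vals, PROJ))
        table = region_areas(iso, RegionSet({}))
        assert list(table.region) == ["unassigned"]


class TestTabulation:
    def test_percent_columns_sum_to_100_with_unassigned(self):
        t = tabulate_region_use({"A": 30.0, "B": 10.0}, {"A": 5.0, "B": 15.0},
                                total_high=50.0, total_moderate=25.0)
        assert t.high_use_pct.sum() == pytest.approx(100.0)
        assert t.moderate_use_pct.sum() == pytest.approx(100.0)
        assert "unassigned" in set(t.region)

    def test_dense_ranks_skip_zeros(self):
        t = tabulate_region_use({"A": 30.0, "B": 0.0, "C": 10.0},
                                {"A": 0.0, "B": 0.0, "C": 0.0})
        t = t.set_index("region")
        assert t.loc["A", "high_use_rank"] == 1
        assert t.loc["C", "high_use_rank"] == 2
        assert t.loc["B", "high_use_rank"] == 0
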