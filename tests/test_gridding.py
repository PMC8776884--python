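"""Effort gridding, log-normal cell classes, period comparison, barycentres."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from fleetres.ais import detect_fishing_points, fishing_hours, flag_fleet, segment_trips
from fleetres.gridding import (
    BarycentrePoint,
    EffortGrid,
    barycentre_extent,
    classify_cells_lognormal,
    classify_values_lognormal,
    compare_periods,
    fishing_intervals,
    grid_effort,
    monthly_barycentre,
    snap_to_cell,
)
from .test_ais import make_trip


def grid_from_cells(cells, resolution=0.1, **kw):
    df = pd.DataFrame(cells, columns=["lon_min", "lat_min", "hours"])
    return EffortGrid(resolution, df, **kw)


def uniform_grid(n_cells, total_hours, resolution=0.5, lat0=40.0):
    cells = [
        (round(i * resolution, 6), lat0, total_hours / n_cells) for i in range(n_cells)
    ]
    return grid_from_cells(cells, resolution)


class TestGridEffort:
    def _intervals(self, lon, lat, hours=1.0):
        return pd.DataFrame(
            {"vessel_id": "A", "trip_id": "A-1", "timestamp": pd.to_datetime("2020-01-01", utc=True),
             "lat": [lat], "lon": [lon], "hours": [hours]}
        )

    def test_half_open_binning(self):
        g = grid_effort(self._intervals(13.07, 43.04), resolution=0.1)
        assert g.cells.iloc[0][["lon_min", "lat_min"]].tolist() == [13.0, 43.0]
        assert g.total_hours == pytest.approx(1.0)

    def test_edge_point_belongs_to_upper_cell(self):
        g = grid_effort(self._intervals(13.1, 43.0), resolution=0.1)
        assert g.cells.iloc[0][["lon_min", "lat_min"]].tolist() == [13.1, 43.0]

    def test_negative_resolution_rejected(self):
        with pytest.raises(ValueError):
            grid_effort(self._intervals(13.0, 43.0), resolution=-0.1)

    def test_conservation_against_trip_hours(self, demo_pings):
        gear_map = {v: v[:-2] for v in demo_pings["vessel_id"].unique()}
        flagged = flag_fleet(demo_pings, gear_map)
        total_by_trips = sum(
            fishing_hours(detect_fishing_points(t, gear_map[t.vessel_id]))
            for t in segment_trips(demo_pings)
        )
        grid = grid_effort(fishing_intervals(flagged), resolution=0.1)
        assert grid.total_hours == pytest.approx(total_by_trips, rel=1e-9)

    def test_interval_hours_equal_flagged_pair_gaps(self):
        t = detect_fishing_points(make_trip([3.2] * 13), "OTB")
        p = t.pings.assign(trip_id=t.trip_id)
        iv = fishing_intervals(p)
        assert iv["hours"].sum() == pytest.approx(fishing_hours(t), rel=1e-9)


class TestLognormalClasses:
    def test_hand_computed_thresholds(self):
        vals = pd.Series([10.0, 100.0, 1000.0])
        assert list(classify_values_lognormal(vals)) == ["MEDIUM", "MEDIUM", "HIGH"]

    def test_equal_cells_all_medium(self):
        vals = pd.Series([42.0] * 8)
        assert set(classify_values_lognormal(vals)) == {"MEDIUM"}

    def test_high_fraction_matches_normal_tail(self):
        """On a large log-normal sample the HIGH share approaches P(Z >= 1)."""
        rng = np.random.default_rng(0)
        vals = pd.Series(10 ** rng.normal(2.0, 0.8, 10_000))
        classes = classify_values_lognormal(vals)
        assert (classes == "HIGH").mean() == pytest.approx(0.1587, abs=0.01)
        assert (classes == "LOW").mean() == pytest.approx(0.1587, abs=0.01)

    def test_reference_grid_thresholds_apply(self):
        ref = grid_from_cells([(0.0, 0.0, 10.0), (0.1, 0.0, 100.0), (0.2, 0.0, 1000.0)])
        tgt = grid_from_cells([(0.0, 0.0, 2000.0), (0.1, 0.0, 5.0)])
        out = classify_cells_lognormal(tgt, reference=ref)
        assert list(out.cells["effort_class"]) == ["HIGH", "LOW"]

    def test_quantile_method(self):
        vals = pd.Series(np.arange(1.0, 10.0))
        classes = classify_values_lognormal(vals, method="quantile")
        assert list(classes[:3]) == ["LOW", "LOW", "LOW"]
        assert list(classes[-3:]) == ["HIGH", "HIGH", "HIGH"]

    def test_no_positive_cells_rejected(self):
        with pytest.raises(ValueError):
            classify_values_lognormal(pd.Series([0.0, 0.0]))

    def test_monotone_in_cell_hours(self):
        """Raising one cell's hours under a fixed reference never demotes it."""
        ref = pd.Series(10 ** np.linspace(0, 3, 20))
        order = {"LOW": 0, "MEDIUM": 1, "HIGH": 2}
        prev = -1
        for h in [1.0, 10.0, 100.0, 1000.0, 10000.0]:
            cls = classify_values_lognormal(pd.Series([h]), reference=ref)[0]
            assert order[cls] >= prev
            prev = order[cls]


class TestComparePeriods:
    def test_reported_effort_change_between_years(self):
        a = uniform_grid(316, 674_000.0)
        b = uniform_grid(335, 649_000.0)
        s = compare_periods(a, b)
        assert s["hours_diff"] == pytest.approx(-25_000.0)
        assert s["pct_change"] == pytest.approx(-3.71, abs=0.01)
        assert s["cells_diff"] == 19

    def test_identical_grids_no_change(self):
        a = uniform_grid(10, 100.0)
        s = compare_periods(a, uniform_grid(10, 100.0))
        assert s["hours_diff"] == 0.0 and s["cells_diff"] == 0
        assert (s["per_cell"]["diff"] == 0).all()

    def test_empty_second_grid(self):
        a = uniform_grid(5, 100.0)
        b = grid_from_cells([(0.0, 40.0, 0.0)], resolution=0.5)
        s = compare_periods(a, b)
        assert s["pct_change"] == pytest.approx(-100.0)

    def test_resolution_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_periods(uniform_grid(3, 10.0, resolution=0.5), uniform_grid(3, 10.0, resolution=0.1))


class TestBarycentre:
    def test_single_cell_is_its_centre(self):
        g = grid_from_cells([(13.0, 43.0, 5.0)])
        b = monthly_barycentre(g)
        assert (b.lon, b.lat) == (pytest.approx(13.05), pytest.approx(43.05))

    def test_equal_weights_midpoint(self):
        g = grid_from_cells([(13.0, 43.0, 5.0), (13.2, 43.0, 5.0)])
        b = monthly_barycentre(g)
        assert b.lon == pytest.approx(13.15)

    def test_weighted_mean_hand_value(self):
        g = grid_from_cells([(13.0, 43.0, 100.0), (13.1, 43.0, 300.0)])
        b = monthly_barycentre(g)
        assert b.lon == pytest.approx(13.125)
        assert b.lat == pytest.approx(43.05)
        assert b.total_hours == pytest.approx(400.0)

    def test_all_zero_grid_rejected(self):
        with pytest.raises(ValueError):
            monthly_barycentre(grid_from_cells([(13.0, 43.0, 0.0)]))

    def test_inside_convex_hull(self):
        rng = np.random.default_rng(5)
        cells = [(round(0.1 * i, 2), round(0.1 * j, 2), rng.uniform(0, 10))
                 for i in range(5) for j in range(5)]
        g = grid_from_cells(cells)
        b = monthly_barycentre(g)
        assert 0.05 <= b.lon <= 0.45 and 0.05 <= b.lat <= 0.45

    @given(dlon=st.floats(-5, 5), dlat=st.floats(-5, 5))
    def test_translation_equivariance(self, dlon, dlat):
        cells = [(13.0, 43.0, 100.0), (13.1, 43.2, 300.0)]
        b0 = monthly_barycentre(grid_from_cells(cells))
        shifted = [(lo + dlon, la + dlat, h) for lo, la, h in cells]
        b1 = monthly_barycentre(grid_from_cells(shifted))
        assert b1.lon == pytest.approx(b0.lon + dlon, abs=1e-9)
        assert b1.lat == pytest.approx(b0.lat + dlat, abs=1e-9)


class TestBarycentreExtent:
    def _pt(self, lon, lat, gear="PTM", period="2020-01"):
        return BarycentrePoint(gear, period, lon, lat, 100.0)

    def test_single_point_degenerate(self):
        e = barycentre_extent([self._pt(13.0, 43.0)])
        assert e["lat_range"] == 0.0

    def test_latitudinal_range(self):
        e = barycentre_extent([self._pt(13.0, 43.0), self._pt(13.5, 44.0)])
        assert e["lat_range"] == pytest.approx(1.0)

    def test_wide_ranging_fleet_has_larger_extent(self):
        ptm = [self._pt(13.0, 43.0 + 2.0 * np.sin(m / 2)) for m in range(12)]
        tbb = [self._pt(13.0, 43.0 + 1.0 * np.sin(m / 2), gear="TBB") for m in range(12)]
        assert barycentre_extent(ptm)["lat_range"] > barycentre_extent(tbb)["lat_range"]


def test_snap_to_cell_half_open_convention():
    assert snap_to_cell([13.07, 13.1, 12.999999], 0.1).tolist() == [13.0, 13.1, 12.9]
    assert snap_to_cell([-0.05], 0.1).tolist() == [-0.1]
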