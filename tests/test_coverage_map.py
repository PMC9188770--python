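"""Grid tessellation, binning, projection, GeoJSON export, date filter."""

import json
from datetime import date, datetime

import numpy as np
import pytest

from sargamap import (
    BinScale,
    GeoPhotoRecord,
    GridSpec,
    aggregate,
    assign_cell,
    export_map,
    from_utm,
    temporal_filter,
    to_utm,
    utm_zone,
)

ZONE = 16  # study-area zone (Mahahual, Quintana Roo)


def record_at(easting, northing, coverage, image_id="x", ts=None):
    """Synthesize a WGS84 record at exact UTM coordinates."""
    lat, lon = from_utm(easting, northing, ZONE)
    return GeoPhotoRecord(image_id, lat, lon, ts, coverage)


class TestProjection:
    def test_zone_selection(self):
        assert utm_zone(-87.708009) == 16
        assert utm_zone(0.5) == 31
        assert utm_zone(-180.0) == 1

    def test_central_meridian_maps_to_false_easting(self):
        x, y, _ = to_utm(18.7, -87.0, zone=16)  # zone 16 central meridian 87W
        assert x == pytest.approx(500000.0, abs=1e-6)

    def test_equator_has_zero_northing(self):
        _, y, _ = to_utm(0.0, -87.0, zone=16)
        assert y == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("lat,lon", [(18.715693, -87.708009), (0.0, -90.0), (45.0, -85.5)])
    def test_round_trip_identity(self, lat, lon):
        x, y, z = to_utm(lat, lon, zone=16)
        lat2, lon2 = from_utm(x, y, z)
        assert lat2 == pytest.approx(lat, abs=1e-8)
        assert lon2 == pytest.approx(lon, abs=1e-8)

    def test_projected_distance_matches_haversine(self):
        """Projected Euclidean distance between nearby points agrees with
        an independent great-circle (haversine) estimate. Tolerance covers
        the UTM scale factor (0.9996 at the central meridian) and the
        sphere-vs-ellipsoid radius difference (~0.3 %)."""
        lat0, lon0 = 18.715693, -87.708009
        lat1, lon1 = lat0 + 0.003, lon0 + 0.002
        x0, y0, _ = to_utm(lat0, lon0, ZONE)
        x1, y1, _ = to_utm(lat1, lon1, ZONE)
        dproj = np.hypot(x1 - x0, y1 - y0)
        p0, p1 = np.radians([lat0, lon0]), np.radians([lat1, lon1])
        dhav = 2 * 6371008.8 * np.arcsin(
            np.sqrt(
                np.sin((p1[0] - p0[0]) / 2) ** 2
                + np.cos(p0[0]) * np.cos(p1[0]) * np.sin((p1[1] - p0[1]) / 2) ** 2
            )
        )
        assert dproj == pytest.approx(dhav, rel=7e-3)


class TestAssignCell:
    GRID = GridSpec(utm_zone=ZONE)

    def test_nearby_points_share_a_cell(self):
        a = record_at(450_010.0, 2_070_010.0, 10.0)
        b = record_at(450_011.0, 2_070_010.0, 20.0)
        assert assign_cell(a, self.GRID) == assign_cell(b, self.GRID)

    def test_shared_edge_belongs_to_upper_cell(self):
        """Half-open intervals: a point exactly on x = 30k starts the next
        column (checked on projected coordinates, where edges are exact)."""
        from sargamap.coverage_map import cell_of_xy

        ce = cell_of_xy(450_030.0, 2_070_015.0, self.GRID)
        ci = cell_of_xy(450_029.999, 2_070_015.0, self.GRID)
        assert ce[0] == ci[0] + 1 and ce[1] == ci[1]

    def test_31_m_apart_are_adjacent_columns(self):
        a = record_at(450_005.0, 2_070_015.0, 10.0)
        b = record_at(450_036.0, 2_070_015.0, 10.0)
        ca, cb = assign_cell(a, self.GRID), assign_cell(b, self.GRID)
        assert cb[0] - ca[0] == 1 and cb[1] == ca[1]

    def test_origin_override_shifts_grid(self):
        rec = record_at(450_010.0, 2_070_010.0, 10.0)
        shifted = GridSpec(utm_zone=ZONE, origin_x=15.0, origin_y=0.0)
        assert assign_cell(rec, shifted) != assign_cell(rec, self.GRID)


class TestBinScale:
    @pytest.mark.parametrize(
        "value,expect",
        [
            (0.0, 1),
            (20.0, 1),
            (20.01, 2),
            (40.0, 2),
            (50.0, 3),
            (60.0, 3),
            (80.0, 4),
            (80.01, 5),
            (100.0, 5),
        ],
    )
    def test_interval_closure(self, value, expect):
        assert BinScale().bin_of(value) == expect

    def test_monotone(self):
        scale = BinScale()
        vals = np.linspace(0, 100, 1001)
        bins = [scale.bin_of(v) for v in vals]
        assert all(b2 >= b1 for b1, b2 in zip(bins, bins[1:]))

    def test_five_distinct_colors(self):
        assert len(set(BinScale().colors)) == 5

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            BinScale().bin_of(100.1)


class TestAggregate:
    def test_mean_and_bin_per_cell(self):
        recs = [
            record_at(450_005.0, 2_070_005.0, 40.0),
            record_at(450_010.0, 2_070_010.0, 60.0),
        ]
        (cell,) = aggregate(recs, GridSpec(utm_zone=ZONE))
        assert cell.mean_coverage == pytest.approx(50.0)
        assert cell.bin == 3
        assert cell.n_photos == 2

    def test_extreme_coverages_hit_extreme_bins(self):
        (hi,) = aggregate([record_at(0.0, 0.0, 100.0)], GridSpec(utm_zone=ZONE))
        (lo,) = aggregate([record_at(0.0, 0.0, 0.0)], GridSpec(utm_zone=ZONE))
        assert hi.bin == 5 and lo.bin == 1

    def test_photo_count_conservation(self):
        rng = np.random.default_rng(0)
        recs = [
            record_at(
                450_000 + float(rng.uniform(0, 300)),
                2_070_000 + float(rng.uniform(0, 300)),
                float(rng.uniform(0, 100)),
                f"p{i}",
            )
            for i in range(57)
        ]
        cells = aggregate(recs, GridSpec(utm_zone=ZONE))
        assert sum(c.n_photos for c in cells) == 57
        for c in cells:
            assert min(c.member_coverages) <= c.mean_coverage <= max(c.member_coverages)

    def test_empty_input_empty_output(self):
        assert aggregate([], GridSpec(utm_zone=ZONE)) == []

    def test_undefined_coverage_rejected(self):
        rec = GeoPhotoRecord("u", 18.7, -87.7, None, None)
        with pytest.raises(ValueError):
            aggregate([rec], GridSpec(utm_zone=ZONE))

    def test_grid_partition_no_gaps_no_overlaps(self):
        """Adjacent cells share edges exactly in the projected CRS."""
        recs = [
            record_at(450_005.0, 2_070_005.0, 10.0),
            record_at(450_035.0, 2_070_005.0, 20.0),
        ]
        c0, c1 = aggregate(recs, GridSpec(utm_zone=ZONE))
        # right edge of c0 == left edge of c1
        right = {(x, y) for x, y in c0.polygon_utm if x == max(p[0] for p in c0.polygon_utm)}
        left = {(x, y) for x, y in c1.polygon_utm if x == min(p[0] for p in c1.polygon_utm)}
        assert right == left


class TestExport:
    def test_empty_collection_is_valid(self, tmp_path):
        paths = export_map([], [], tmp_path)
        data = json.loads(paths["grid"].read_text())
        assert data == {"type": "FeatureCollection", "features": []}

    def test_polygon_ring_closed_and_round_trips(self, tmp_path):
        recs = [record_at(450_005.0, 2_070_005.0, 35.0, "a")]
        cells = aggregate(recs, GridSpec(utm_zone=ZONE))
        paths = export_map(cells, recs, tmp_path)
        feat = json.loads(paths["grid"].read_text())["features"][0]
        ring = feat["geometry"]["coordinates"][0]
        assert len(ring) == 5 and ring[0] == ring[-1]
        for (lon, lat), (elon, elat) in zip(ring[:-1], cells[0].polygon_wgs84):
            assert lon == pytest.approx(elon, abs=1e-8)
            assert lat == pytest.approx(elat, abs=1e-8)
        props = feat["properties"]
        assert props["n_photos"] == 1 and props["bin"] == 2

    def test_point_layer_presence_flags(self, tmp_path):
        recs = [
            record_at(0.0, 0.0, 0.0, "absent"),
            record_at(10.0, 10.0, 55.0, "present"),
        ]
        paths = export_map([], recs, tmp_path)
        feats = json.loads(paths["photos"].read_text())["features"]
        flags = {f["properties"]["image_id"]: f["properties"]["presence"] for f in feats}
        assert flags == {"absent": False, "present": True}

    def test_deterministic_feature_order(self, tmp_path):
        rng = np.random.default_rng(1)
        recs = [
            record_at(
                450_000 + float(rng.uniform(0, 200)),
                2_070_000 + float(rng.uniform(0, 200)),
                50.0,
                f"p{i}",
            )
            for i in range(20)
        ]
        cells = aggregate(recs, GridSpec(utm_zone=ZONE))
        a = export_map(cells, recs, tmp_path / "a")["grid"].read_text()
        b = export_map(list(reversed(cells)), recs, tmp_path / "b")["grid"].read_text()
        assert a == b


class TestTemporalFilter:
    def recs(self):
        return [
            record_at(0, 0, 10.0, "a", datetime(2019, 9, 14, 10)),
            record_at(0, 0, 20.0, "b", datetime(2020, 12, 16, 12)),
            record_at(0, 0, 30.0, "c", datetime(2021, 8, 24, 14)),
        ]

    def test_full_range_is_identity(self):
        recs = self.recs()
        assert temporal_filter(recs, (date(2019, 9, 14), date(2021, 8, 24))) == recs

    def test_empty_intersection(self):
        assert temporal_filter(self.recs(), (date(2022, 1, 1), date(2022, 2, 1))) == []

    def test_single_day(self):
        got = temporal_filter(self.recs(), (date(2020, 12, 16), date(2020, 12, 16)))
        assert [r.image_id for r in got] == ["b"]

    def test_missing_timestamp_rejected(self):
        rec = GeoPhotoRecord("x", 0.0, 0.0, None, 5.0)
        with pytest.raises(ValueError):
            temporal_filter([rec], (date(2020, 1, 1), date(2020, 1, 2)))
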