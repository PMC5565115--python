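"""AIS filtering, track building, clipping and transit-time tests."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString

from strikerisk.ais import (
    KNOT_TO_KMH,
    build_tracks,
    cell_track_stats,
    filter_records,
    read_ais_csv,
    transit_time,
)
from strikerisk.grid import AnalysisGrid
from strikerisk.projection import AlbersEqualArea


def make_records(rows):
    cols = ["vessel_id", "timestamp", "lon", "lat", "sog_kn", "draft_m",
            "beam_m", "vessel_type", "nav_status"]
    df = pd.DataFrame(rows, columns=cols)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


BASE = ["v1", "2014-07-01T00:00:00", -124.0, 36.0, 12.0, 9.0, 30.0, "cargo", "underway"]


def variant(**kw):
    row = dict(zip(["vessel_id", "timestamp", "lon", "lat", "sog_kn", "draft_m",
                    "beam_m", "vessel_type", "nav_status"], BASE))
    row.update(kw)
    return list(row.values())


class TestFilter:
    def test_clean_cargo_kept(self):
        out = filter_records(make_records([BASE]))
        assert len(out) == 1

    def test_shallow_draft_removed(self):
        out = filter_records(make_records([variant(draft_m=0.5)]))
        assert len(out) == 0
        assert out.attrs["filter_report"].removed_shallow_draft == 1

    def test_slow_ping_removed(self):
        out = filter_records(make_records([variant(sog_kn=0.5)]))
        assert len(out) == 0
        assert out.attrs["filter_report"].removed_slow == 1

    def test_disallowed_type_removed(self):
        out = filter_records(make_records([variant(vessel_type="fishing")]))
        assert len(out) == 0

    def test_not_underway_removed(self):
        out = filter_records(make_records([variant(nav_status="moored")]))
        assert len(out) == 0

    def test_idempotent(self):
        df = make_records([BASE, variant(sog_kn=0.2), variant(draft_m=0.3),
                           variant(vessel_type="fishing")])
        once = filter_records(df)
        twice = filter_records(once)
        pd.testing.assert_frame_equal(once, twice)


class TestTracks:
    def test_three_pings_one_track(self):
        rows = [variant(timestamp=f"2014-07-01T00:{m:02d}:00", lon=-124.0 + m * 0.01)
                for m in (0, 10, 20)]
        tracks = build_tracks(make_records(rows), AlbersEqualArea())
        assert len(tracks) == 1
        assert len(tracks[0].xy) == 3

    def test_gap_splits_voyage(self):
        rows = [variant(timestamp="2014-07-01T00:00:00"),
                variant(timestamp="2014-07-01T12:00:00")]
        tracks = build_tracks(make_records(rows), AlbersEqualArea(),
                              max_gap=pd.Timedelta(hours=6))
        assert len(tracks) == 2
        assert all(t.length_km == 0.0 for t in tracks)

    def test_vessels_not_mixed(self):
        rows = [variant(vessel_id="a", timestamp="2014-07-01T00:00:00"),
                variant(vessel_id="b", timestamp="2014-07-01T00:01:00"),
                variant(vessel_id="a", timestamp="2014-07-01T00:10:00", lon=-124.01),
                variant(vessel_id="b", timestamp="2014-07-01T00:11:00", lon=-123.99)]
        tracks = build_tracks(make_records(rows), AlbersEqualArea())
        assert len(tracks) == 2
        assert {t.vessel_id for t in tracks} == {"a", "b"}


class FakeTrack:
    """Synthetic projected track for geometry tests."""

    def __init__(self, xy, voyage_id="t0"):
        self.xy = np.asarray(xy, dtype=float)
        self.voyage_id = voyage_id


class TestCellClipping:
    def grid(self):
        return AnalysisGrid(0, 0, 3, 3, cell_size=12_000.0)

    def test_straight_crossing_one_cell(self):
        g = self.grid()
        # horizontal line through the middle cell row
        tr = FakeTrack([(12_000, 18_000), (24_000, 18_000)])
        stats = cell_track_stats([tr], g)
        cell = g.locate(18_000, 18_000)
        assert stats.loc[cell, "track_length_km"] == pytest.approx(12.0)
        assert stats.loc[cell, "n_voyages"] == 1

    def test_two_voyages_double_length(self):
        g = self.grid()
        trs = [FakeTrack([(12_000, 18_000), (24_000, 18_000)], f"t{i}") for i in range(2)]
        stats = cell_track_stats(trs, g)
        cell = g.locate(18_000, 18_000)
        assert stats.loc[cell, "track_length_km"] == pytest.approx(24.0)
        assert stats.loc[cell, "n_voyages"] == 2

    def test_diagonal_crossing(self):
        g = self.grid()
        tr = FakeTrack([(12_000, 12_000), (24_000, 24_000)])
        stats = cell_track_stats([tr], g)
        cell = g.locate(18_000, 18_000)
        assert stats.loc[cell, "track_length_km"] == pytest.approx(12 * np.sqrt(2), rel=1e-9)

    def test_length_conserved_under_clipping(self, rng):
        g = self.grid()
        # random polylines fully inside the grid
        tracks = []
        for i in range(10):
            pts = rng.uniform(0, 36_000, size=(5, 2))
            tracks.append(FakeTrack(pts, f"t{i}"))
        stats = cell_track_stats(tracks, g)
        total = sum(LineString(t.xy).length / 1000.0 for t in tracks)
        assert stats["track_length_km"].sum() == pytest.approx(total, rel=1e-6)

    def test_outside_grid_contributes_nothing(self):
        g = self.grid()
        tr = FakeTrack([(100_000, 100_000), (120_000, 120_000)])
        stats = cell_track_stats([tr], g)
        assert stats["track_length_km"].sum() == 0.0
        assert stats["n_voyages"].sum() == 0


class TestTransitTime:
    def test_single_voyage_either_convention(self):
        kn = 20.0 / KNOT_TO_KMH  # 20 km/h expressed in knots
        assert transit_time(100.0, kn, 1, "per_vessel") == pytest.approx(5.0)
        assert transit_time(100.0, kn, 1, "total") == pytest.approx(5.0)

    def test_zero_length(self):
        assert transit_time(0.0, 10.0, 3) == 0.0

    def test_per_vessel_times_nb_recovers_fleet_time(self):
        kn = 20.0 / KNOT_TO_KMH
        t = transit_time(100.0, kn, 4, "per_vessel")
        assert t == pytest.approx(1.25)
        assert t * 4 == pytest.approx(5.0)

    def test_zero_speed_rejected(self):
        with pytest.raises(ValueError):
            transit_time(10.0, 0.0, 1)


def test_read_ais_csv_marinecadastre_headers(tmp_path):
    p = tmp_path / "ais.csv"
    p.write_text(
        "MMSI,BaseDateTime,LAT,LON,SOG,VesselType,Draft,Width,Status\n"
        "123,2014-07-01T00:00:00,36.0,-124.0,12.0,cargo,9.0,30.0,underway\n"
        "124,not-a-date,36.0,-124.0,12.0,cargo,9.0,30.0,underway\n"
    )
    df = read_ais_csv(p)
    assert list(df.columns[:2]) == ["vessel_id", "timestamp"]
    assert len(df) == 1  # unparseable timestamp dropped
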