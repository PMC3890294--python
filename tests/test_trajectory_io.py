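"""Trajectory and series file round trips and the recording-time filter."""

import numpy as np
import pytest

from mobiscale.series import DisplacementSeries
from mobiscale.synthetic_data import generate_trajectory, random_itinerary
from mobiscale.trajectory_io import (EmptyTrajectoryError, SeriesFormatError,
                                     TrackPoint, Trajectory, filter_files,
                                     read_plt, read_series, write_plt,
                                     write_series)

PLT_HEADER = ("Geolife trajectory\nWGS 84\nAltitude is in Feet\nReserved 3\n"
              "0,2,255,My Track,0,0,2,8421376\n0\n")


def _plt(tmp_path, body, name="20081023025304.plt"):
    d = tmp_path / "001" / "Trajectory"
    d.mkdir(parents=True, exist_ok=True)
    path = d / name
    path.write_text(PLT_HEADER + body)
    return path


class TestReadPlt:
    def test_identity_parse(self, tmp_path):
        body = ("39.906631,116.385564,0,492,39925.4486111111,2009-04-22,10:46:00\n"
                "39.906554,116.385625,0,492,39925.4486226852,2009-04-22,10:46:01\n"
                "39.906558,116.385483,0,493,39925.4486342593,2009-04-22,10:46:02\n")
        traj = read_plt(_plt(tmp_path, body))
        assert traj.user_id == "001"
        assert len(traj) == 3
        assert traj.points[0].latitude == pytest.approx(39.906631)
        assert traj.points[0].longitude == pytest.approx(116.385564)
        assert traj.points[1].timestamp - traj.points[0].timestamp == 1.0
        # altitude converted from feet to meters
        assert traj.points[0].altitude == pytest.approx(492 * 0.3048)

    def test_corrupt_line_skipped(self, tmp_path, caplog):
        good = "39.9,116.3,0,100,39925.0,2009-04-22,10:46:{:02d}\n"
        body = "".join(good.format(i) for i in range(3))
        body += "not,a,valid,record,at,all\n" + good.format(10)
        with caplog.at_level("WARNING"):
            traj = read_plt(_plt(tmp_path, body))
        assert len(traj) == 4
        assert "1 malformed" in caplog.text

    def test_empty_file_raises(self, tmp_path):
        with pytest.raises(EmptyTrajectoryError):
            read_plt(_plt(tmp_path, ""))

    def test_out_of_order_records_sorted(self, tmp_path):
        line = "39.9,116.3,0,100,0,2009-04-22,10:46:{:02d}\n"
        traj = read_plt(_plt(tmp_path, line.format(30) + line.format(10)))
        ts = [p.timestamp for p in traj.points]
        assert ts == sorted(ts)

    def test_roundtrip_preserves_coordinates(self, tmp_path):
        plan = random_itinerary(n_staypoints=3, seed=2)
        traj, _ = generate_trajectory(plan, seed=2)
        path = tmp_path / "rt.plt"
        write_plt(traj, path)
        back = read_plt(path, user_id=traj.user_id, file_id=traj.file_id)
        assert len(back) == len(traj)
        for a, b in zip(traj.points, back.points):
            assert a.latitude == pytest.approx(b.latitude, abs=1e-6)
            assert a.longitude == pytest.approx(b.longitude, abs=1e-6)
            assert a.timestamp == b.timestamp


def _traj_hours(hours, uid="u"):
    pts = [TrackPoint(latitude=10.0, longitude=20.0, timestamp=0.0),
           TrackPoint(latitude=10.0, longitude=20.0, timestamp=hours * 3600.0)]
    return Trajectory(user_id=uid, file_id=f"{hours}h", points=pts)


class TestFilterFiles:
    def test_six_hour_threshold(self):
        kept = filter_files([_traj_hours(5), _traj_hours(7)], 6 * 3600.0)
        assert [t.file_id for t in kept] == ["7h"]

    def test_zero_threshold_keeps_all(self):
        trajs = [_traj_hours(h) for h in range(1, 4)]
        assert filter_files(trajs, 0.0) == trajs

    def test_count_by_construction(self):
        trajs = [_traj_hours(h) for h in range(1, 11)]
        assert len(filter_files(trajs, 6 * 3600.0)) == 5

    def test_idempotent(self):
        trajs = [_traj_hours(h) for h in range(1, 11)]
        once = filter_files(trajs, 6 * 3600.0)
        assert filter_files(once, 6 * 3600.0) == once

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_files([], -1.0)


class TestSeriesFiles:
    def _series(self, n, seed=0, uid="u1", fid="f1"):
        rng = np.random.default_rng(seed)
        return DisplacementSeries.from_displacements(
            rng.uniform(1, 1e4, n), user_id=uid, file_id=fid,
            elapsed_times=rng.uniform(10, 1e3, n),
            staytimes=rng.uniform(120, 1e4, n))

    def test_roundtrip_identity(self, tmp_path):
        orig = [self._series(5, 1, "u1", "a"), self._series(8, 2, "u2", "b")]
        path = tmp_path / "series.tsv"
        write_series(orig, path)
        back = read_series(path)
        assert [(s.user_id, s.file_id, len(s)) for s in back] == \
               [("u1", "a", 5), ("u2", "b", 8)]
        for a, b in zip(orig, back):
            np.testing.assert_allclose(a.displacements, b.displacements,
                                       rtol=1e-9)
            np.testing.assert_allclose(a.staytimes, b.staytimes, rtol=1e-9)

    def test_empty_series_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_series([], path)
        assert path.read_text().count("\n") == 1
        assert read_series(path) == []

    def test_rewrite_byte_stable(self, tmp_path):
        big = self._series(1000, 3)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_series(big, p1)
        write_series(read_series(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_schema_mismatch(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("foo\tbar\n1\t2\n")
        with pytest.raises(SeriesFormatError):
            read_series(path)
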