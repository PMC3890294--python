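"""Reading and writing GPS trajectories and derived series.

Trajectories arrive as Geolife-style PLT files: a fixed six-line header
followed by comma-separated records of latitude, longitude, a constant
field, altitude in feet, fractional days since 1899-12-30, and separate
date and time strings.  Timestamps are taken from the date+time strings
and treated as UTC.  Altitude is parsed but ignored by every downstream
computation, which works on planar (lat, lon) positions only.

Derived movement series are stored as tab-separated tables with a header
so that every analysis stage can be re-run from the stored artifacts.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLT_HEADER_LINES = 6
#: Epoch of the PLT fractional-day field.
_PLT_DAY0 = datetime(1899, 12, 30, tzinfo=timezone.utc)

#: Default minimum per-file recording time (seconds): files spanning less
#: than six hours rarely contain enough dwells to be analysable.
MIN_FILE_DURATION = 6 * 3600.0


@dataclass(frozen=True)
class TrackPoint:
    """One GPS record: position in degrees, altitude in meters, UTC seconds."""

    latitude: float
    longitude: float
    timestamp: float
    altitude: float | None = None

    def __post_init__(self) -> None:
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not (-180.0 <= self.longitude <= 180.0):
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass
class Trajectory:
    """A time-ordered GPS track from a single file of a single user."""

    user_id: str
    file_id: str
    points: list[TrackPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        ts = [p.timestamp for p in self.points]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError("trajectory timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def duration(self) -> float:
        """Recording time in seconds: last minus first timestamp."""
        if not self.points:
            return 0.0
        return self.points[-1].timestamp - self.points[0].timestamp

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(latitudes, longitudes, timestamps) as float arrays."""
        lat = np.array([p.latitude for p in self.points], dtype=float)
        lon = np.array([p.longitude for p in self.points], dtype=float)
        ts = np.array([p.timestamp for p in self.points], dtype=float)
        return lat, lon, ts


class EmptyTrajectoryError(ValueError):
    """Raised when a trajectory file yields no valid records."""


class SeriesFormatError(ValueError):
    """Raised when a stored series file does not match the expected schema."""


_FEET_TO_M = 0.3048


def _parse_plt_line(line: str) -> TrackPoint | None:
    parts = line.strip().split(",")
    if len(parts) < 7:
        return None
    try:
        lat = float(parts[0])
        lon = float(parts[1])
        alt_ft = float(parts[3])
        dt = datetime.strptime(parts[5] + " " + parts[6], "%Y-%m-%d %H:%M:%S")
    except ValueError:
        return None
    if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
        return None
    ts = dt.replace(tzinfo=timezone.utc).timestamp()
    # Geolife uses -777 as a missing-altitude sentinel.
    alt = None if alt_ft <= -700 else alt_ft * _FEET_TO_M
    return TrackPoint(latitude=lat, longitude=lon, timestamp=ts, altitude=alt)


def read_plt(path: str | os.PathLike, user_id: str | None = None,
             file_id: str | None = None) -> Trajectory:
    """Parse one PLT file into a chronologically ordered :class:`Trajectory`.

    Malformed lines are skipped and counted in a log message.  Raises
    :class:`EmptyTrajectoryError` if no line parses.
    """
    path = os.fspath(path)
    if user_id is None:
        # Geolife layout: <user>/Trajectory/<file>.plt
        parent = os.path.dirname(os.path.dirname(os.path.abspath(path)))
        user_id = os.path.basename(parent)
    if file_id is None:
        file_id = os.path.splitext(os.path.basename(path))[0]

    points: list[TrackPoint] = []
    skipped = 0
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for i, line in enumerate(fh):
            if i < PLT_HEADER_LINES:
                continue
            if not line.strip():
                continue
            pt = _parse_plt_line(line)
            if pt is None:
                skipped += 1
            else:
                points.append(pt)
    if skipped:
        logger.warning("%s: skipped %d malformed line(s)", path, skipped)
    if not points:
        raise EmptyTrajectoryError(f"{path}: no valid GPS records")
    points.sort(key=lambda p: p.timestamp)
    return Trajectory(user_id=user_id, file_id=file_id, points=points)


def write_plt(trajectory: Trajectory, path: str | os.PathLike) -> None:
    """Write a trajectory in the PLT dialect read by :func:`read_plt`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("Geolife trajectory\nWGS 84\nAltitude is in Feet\nReserved 3\n"
                 "0,2,255,My Track,0,0,2,8421376\n0\n")
        for p in trajectory.points:
            dt = datetime.fromtimestamp(p.timestamp, tz=timezone.utc)
            days = (dt - _PLT_DAY0).total_seconds() / 86400.0
            alt_ft = -777.0 if p.altitude is None else p.altitude / _FEET_TO_M
            fh.write(f"{p.latitude:.6f},{p.longitude:.6f},0,{alt_ft:.1f},"
                     f"{days:.10f},{dt:%Y-%m-%d},{dt:%H:%M:%S}\n")


def iter_plt_files(indir: str | os.PathLike) -> Iterable[str]:
    """Yield PLT file paths under a Geolife-style directory tree, sorted."""
    out = []
    for root, _dirs, files in os.walk(indir):
        for name in files:
            if name.lower().endswith(".plt"):
                out.append(os.path.join(root, name))
    return sorted(out)


def read_directory(indir: str | os.PathLike) -> list[Trajectory]:
    """Read every PLT file under ``indir``; unreadable files are skipped."""
    trajectories = []
    for path in iter_plt_files(indir):
        try:
            trajectories.append(read_plt(path))
        except EmptyTrajectoryError:
            logger.warning("%s: empty, skipped", path)
    return trajectories


def filter_files(trajectories: Sequence[Trajectory],
                 min_duration: float = MIN_FILE_DURATION) -> list[Trajectory]:
    """Keep trajectories whose recording time is at least ``min_duration``.

    Recording time is last minus first timestamp.  Order is preserved and
    the operation is idempotent.
    """
    if min_duration < 0:
        raise ValueError("min_duration must be >= 0")
    return [t for t in trajectories if t.duration >= min_duration]


_SERIES_COLUMNS = ["user_id", "file_id", "displacement", "elapsed_time",
                   "speed", "preceding_staytime"]


def write_series(series_list, path: str | os.PathLike) -> None:
    """Write movement series as a tab-separated table (one row per movement)."""
    from .series import DisplacementSeries  # local import: avoid cycle

    if isinstance(series_list, DisplacementSeries):
        series_list = [series_list]
    rows = []
    for s in series_list:
        for r in s.records:
            rows.append((s.user_id, s.file_id, r.displacement, r.elapsed_time,
                         r.speed, r.preceding_staytime))
    df = pd.DataFrame(rows, columns=_SERIES_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_series(path: str | os.PathLike):
    """Read a series table written by :func:`write_series`.

    Returns a list of :class:`~mobiscale.series.DisplacementSeries`, one per
    (user_id, file_id) group, in file order.
    """
    from .series import DisplacementSeries, MovementRecord

    try:
        df = pd.read_csv(path, sep="\t", dtype={"user_id": str, "file_id": str})
    except Exception as exc:  # noqa: BLE001 - normalise to format error
        raise SeriesFormatError(f"{path}: unreadable series file: {exc}") from exc
    if list(df.columns) != _SERIES_COLUMNS:
        raise SeriesFormatError(
            f"{path}: expected columns {_SERIES_COLUMNS}, got {list(df.columns)}")
    out = []
    for (uid, fid), grp in df.groupby(["user_id", "file_id"], sort=False):
        records = [MovementRecord(displacement=row.displacement,
                                  elapsed_time=row.elapsed_time,
                                  speed=row.speed,
                                  preceding_staytime=row.preceding_staytime)
                   for row in grp.itertuples()]
        out.append(DisplacementSeries(user_id=str(uid), file_id=str(fid),
                                      records=records))
    return out
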