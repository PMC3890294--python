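"""Effective staying-position (staypoint) extraction.

A staypoint is a maximal sub-sequence of consecutive GPS records that
stays within a small spatial resolution (default 10 m) for longer than a
minimum duration (default 120 s).  The sub-sequence is summarized by the
arithmetic mean of its member coordinates, its arrival and departure
times, and the staying time (departure minus arrival).

Two spatial criteria are provided:

``consecutive`` (default)
    every pair of consecutive member points is closer than ``d_max``;

``all_pairs``
    every pair of member points (not just consecutive ones) is within
    ``d_max``.

The two readings give identical results on compact dwell clusters but can
differ on slowly drifting tracks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory_io import Trajectory

EARTH_RADIUS_M = 6_371_000.0

#: Spatial resolution of a handheld GPS unit, meters.
DEFAULT_D_MAX = 10.0
#: Typical traffic-signal interval, seconds.
DEFAULT_T_MIN = 120.0


@dataclass(frozen=True)
class StayPoint:
    """An effective staying position.

    ``center_latitude``/``center_longitude`` are the mean member
    coordinates in degrees; ``arrival``/``departure`` are the timestamps of
    the first and last member record; ``staying_time = departure − arrival``.
    """

    center_latitude: float
    center_longitude: float
    arrival: float
    departure: float
    n_members: int

    @property
    def staying_time(self) -> float:
        return self.departure - self.arrival


def haversine_distance(a, b) -> float:
    """Great-circle distance in meters between two (lat, lon) carriers.

    Accepts :class:`~mobiscale.trajectory_io.TrackPoint`, :class:`StayPoint`
    or plain ``(lat, lon)`` pairs, in degrees.
    """
    lat1, lon1 = _latlon(a)
    lat2, lon2 = _latlon(b)
    return float(haversine_arrays(lat1, lon1, lat2, lon2))


def _latlon(obj) -> tuple[float, float]:
    if isinstance(obj, StayPoint):
        return obj.center_latitude, obj.center_longitude
    if hasattr(obj, "latitude"):
        return obj.latitude, obj.longitude
    lat, lon = obj
    return float(lat), float(lon)


def haversine_arrays(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Vectorized haversine distance (meters) on degree inputs."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def extract_staypoints(trajectory: Trajectory,
                       d_max: float = DEFAULT_D_MAX,
                       t_min: float = DEFAULT_T_MIN,
                       criterion: str = "consecutive") -> list[StayPoint]:
    """Extract staypoints from a chronological trajectory.

    Scans left to right; at each start index the qualifying sub-sequence is
    extended greedily as far as the spatial criterion allows.  If the
    extended sub-sequence spans strictly more than ``t_min`` seconds it is
    accepted (it needs at least two records to have a duration), and the
    scan resumes at the first point after it; otherwise the start index
    advances by one.

    Parameters
    ----------
    d_max : float
        Spatial resolution in meters; member distances must be strictly
        below it.
    t_min : float
        Minimum staying time in seconds; the sub-sequence span must be
        strictly above it.
    criterion : {"consecutive", "all_pairs"}
        Whether the distance condition applies to consecutive member pairs
        only, or to every member pair.
    """
    if criterion not in ("consecutive", "all_pairs"):
        raise ValueError(f"unknown criterion {criterion!r}")
    n = len(trajectory)
    if n < 2:
        return []
    lat, lon, ts = trajectory.arrays()
    # consecutive-pair distances, step[i] = d(point i, point i+1)
    step = haversine_arrays(lat[:-1], lon[:-1], lat[1:], lon[1:])

    out: list[StayPoint] = []
    i = 0
    while i < n - 1:
        j = i  # last index of the candidate sub-sequence
        if criterion == "consecutive":
            while j + 1 < n and step[j] < d_max:
                j += 1
        else:
            while j + 1 < n and _within_all(lat, lon, i, j + 1, d_max):
                j += 1
        if j > i and ts[j] - ts[i] > t_min:
            out.append(StayPoint(
                center_latitude=float(np.mean(lat[i:j + 1])),
                center_longitude=float(np.mean(lon[i:j + 1])),
                arrival=float(ts[i]),
                departure=float(ts[j]),
                n_members=j - i + 1,
            ))
            i = j + 1
        else:
            i += 1
    return out


def _within_all(lat, lon, i, k, d_max) -> bool:
    """True if point k is within d_max of every point in [i, k-1]."""
    d = haversine_arrays(lat[i:k], lon[i:k], lat[k], lon[k])
    return bool(np.all(d <= d_max))
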