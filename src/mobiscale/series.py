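"""Displacement / staying-time / elapsed-time series built from staypoints.

For a file with staypoints S_1 … S_N the movement series has N−1 records.
Record i carries:

* displacement Δr — great-circle distance between the centers of S_i and
  S_{i+1};
* elapsed time Δt_e — departure of S_i to arrival of S_{i+1}, the time
  spent on the way (dwell time at both ends excluded);
* speed v = Δr / Δt_e;
* preceding staying time Δt — the staying time of S_i.

Relative displacements Δr′ = Δr / ⟨Δr⟩ divide each displacement by the
user's mean displacement pooled over all of that user's files, so that the
per-user mean of Δr′ is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .staypoint import StayPoint, haversine_distance


@dataclass(frozen=True)
class MovementRecord:
    displacement: float
    elapsed_time: float
    speed: float
    preceding_staytime: float = float("nan")


@dataclass
class DisplacementSeries:
    """Ordered movement records of one trajectory file."""

    user_id: str
    file_id: str
    records: list[MovementRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def displacements(self) -> np.ndarray:
        return np.array([r.displacement for r in self.records], dtype=float)

    @property
    def elapsed_times(self) -> np.ndarray:
        return np.array([r.elapsed_time for r in self.records], dtype=float)

    @property
    def speeds(self) -> np.ndarray:
        return np.array([r.speed for r in self.records], dtype=float)

    @property
    def staytimes(self) -> np.ndarray:
        return np.array([r.preceding_staytime for r in self.records], dtype=float)

    @classmethod
    def from_displacements(cls, displacements, user_id: str = "sim",
                           file_id: str = "0", elapsed_times=None,
                           staytimes=None) -> "DisplacementSeries":
        """Wrap a bare displacement array (e.g. simulator output)."""
        d = np.asarray(displacements, dtype=float)
        te = (np.ones_like(d) if elapsed_times is None
              else np.asarray(elapsed_times, dtype=float))
        st = (np.full_like(d, np.nan) if staytimes is None
              else np.asarray(staytimes, dtype=float))
        records = [MovementRecord(displacement=float(di), elapsed_time=float(ti),
                                  speed=float(di / ti), preceding_staytime=float(si))
                   for di, ti, si in zip(d, te, st)]
        return cls(user_id=user_id, file_id=file_id, records=records)


def build_series(staypoints: Sequence[StayPoint], user_id: str = "",
                 file_id: str = "") -> DisplacementSeries:
    """Build the movement series of one file from its staypoint sequence.

    Fewer than two staypoints yield an empty series (not an error).
    """
    records = []
    for a, b in zip(staypoints, staypoints[1:]):
        dr = haversine_distance(a, b)
        te = b.arrival - a.departure
        if te <= 0:
            # Degenerate: zero travel time between non-overlapping dwells
            # can only come from duplicated timestamps; avoid a 0-division.
            te = float("nan")
        records.append(MovementRecord(displacement=dr, elapsed_time=te,
                                      speed=dr / te,
                                      preceding_staytime=a.staying_time))
    return DisplacementSeries(user_id=user_id, file_id=file_id, records=records)


def pool_population(series_list: Sequence[DisplacementSeries]) -> dict:
    """Concatenate per-file samples over a population of series.

    Returns a dict with pooled ``displacements``, ``staytimes``,
    ``elapsed_times`` and ``speeds`` arrays plus ``per_file`` — the list of
    per-file displacement arrays, in input order, for correlation analyses
    whose index pairs must never span a file boundary.
    """
    disp, stay, elap, spd, per_file = [], [], [], [], []
    for s in series_list:
        d = s.displacements
        per_file.append(d)
        disp.append(d)
        stay.append(s.staytimes)
        elap.append(s.elapsed_times)
        spd.append(s.speeds)
    cat = (lambda parts: np.concatenate(parts) if parts else np.empty(0))
    return {
        "displacements": cat(disp),
        "staytimes": cat(stay),
        "elapsed_times": cat(elap),
        "speeds": cat(spd),
        "per_file": per_file,
    }


def user_mean_displacements(series_list: Sequence[DisplacementSeries]) -> dict:
    """Per-user mean displacement ⟨Δr⟩ pooled over each user's files."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for s in series_list:
        d = s.displacements
        sums[s.user_id] = sums.get(s.user_id, 0.0) + float(d.sum())
        counts[s.user_id] = counts.get(s.user_id, 0) + len(d)
    return {u: sums[u] / counts[u] for u in sums if counts[u] > 0}


def relative_displacements(series_list: Sequence[DisplacementSeries]) -> list[np.ndarray]:
    """Per-file Δr′ = Δr / ⟨Δr⟩ arrays, in input order.

    The pooled mean of Δr′ over each user's records is 1 by construction.
    """
    means = user_mean_displacements(series_list)
    return [s.displacements / means[s.user_id] if len(s) else np.empty(0)
            for s in series_list]


def speed_displacement_points(series_list: Sequence[DisplacementSeries],
                              per_user: bool = False,
                              bins_per_decade: int = 10,
                              split_point: float = 1000.0) -> dict:
    """(Δr, v) point cloud plus a log-binned median-speed curve.

    Each movement contributes one point (default); with ``per_user`` the
    points are per-user mean displacement vs mean speed instead.  The
    binned curve takes per-bin medians of v over log-spaced Δr bins, and a
    two-segment OLS line is fitted in log-log space on either side of
    ``split_point`` (meters), returning both slopes.
    """
    if per_user:
        by_user: dict[str, list] = {}
        for s in series_list:
            by_user.setdefault(s.user_id, []).append(s)
        dr, v = [], []
        for ss in by_user.values():
            d = np.concatenate([s.displacements for s in ss])
            sp = np.concatenate([s.speeds for s in ss])
            ok = np.isfinite(sp)
            if ok.any():
                dr.append(d[ok].mean())
                v.append(sp[ok].mean())
        dr, v = np.asarray(dr), np.asarray(v)
    else:
        pool = pool_population(series_list)
        dr, v = pool["displacements"], pool["speeds"]
        ok = np.isfinite(v)
        dr, v = dr[ok], v[ok]
    pos = dr > 0
    dr_p, v_p = dr[pos], v[pos]

    curve_x, curve_y = _binned_median(dr_p, v_p, bins_per_decade)
    slopes = tuple(
        _loglog_slope(dr_p[m], v_p[m])
        for m in (dr_p < split_point, dr_p >= split_point))
    return {"points": np.column_stack([dr, v]),
            "curve": (curve_x, curve_y),
            "slope_low": slopes[0], "slope_high": slopes[1],
            "split_point": split_point}


def _binned_median(x: np.ndarray, y: np.ndarray, bins_per_decade: int):
    if len(x) == 0:
        return np.empty(0), np.empty(0)
    lo, hi = np.log10(x.min()), np.log10(x.max())
    n_bins = max(1, int(np.ceil((hi - lo) * bins_per_decade)))
    edges = np.logspace(lo, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    centers, med = [], []
    for b in range(n_bins):
        m = idx == b
        if m.any():
            centers.append(np.sqrt(edges[b] * edges[b + 1]))
            med.append(np.median(y[m]))
    return np.asarray(centers), np.asarray(med)


def _loglog_slope(x: np.ndarray, y: np.ndarray) -> float:
    ok = (x > 0) & (y > 0)
    if ok.sum() < 2:
        return float("nan")
    lx, ly = np.log(x[ok]), np.log(y[ok])
    if np.ptp(lx) == 0:
        return float("nan")
    return float(np.polyfit(lx, ly, 1)[0])
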